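"""Plain-text ``key = value`` run configuration for the command line.

Recognised keys: ``A B C D E deescalation dose_probs conf_level``.
``dose_probs`` is a comma-separated list; ``deescalation`` accepts the
usual boolean spellings.  Lines starting with ``#`` and blank lines are
ignored.  Values given on the command line override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .design import DesignSpec, ToxScenario, validate_design

__all__ = ["RunConfig", "parse_config_file"]

_BOOL = {"1": True, "true": True, "yes": True, "on": True,
         "0": False, "false": False, "no": False, "off": False}


@dataclass
class RunConfig:
    """Validated inputs for one evaluation run."""

    design: DesignSpec
    scenario: ToxScenario
    conf_level: float = 0.95
    out_dir: Path = Path("abdesign-out")
    report_format: str = "md"
    overwrite: bool = False
    mc_check: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.conf_level < 1.0):
            raise ValueError(f"conf_level must lie in (0,1), got {self.conf_level}")
        if self.report_format not in ("md", "html"):
            raise ValueError(f"report format must be 'md' or 'html', got {self.report_format!r}")
        if self.mc_check < 0:
            raise ValueError("mc_check must be non-negative")


def parse_config_file(path: str | Path) -> dict:
    """Read a key = value config file into a keyword dictionary."""
    known = {"a", "b", "c", "d", "e", "deescalation", "dose_probs", "conf_level"}
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key in {"a", "b", "c", "d", "e"}:
            out[key.upper()] = int(value)
        elif key == "deescalation":
            if value.lower() not in _BOOL:
                raise ValueError(f"{path}:{lineno}: bad boolean {value!r}")
            out["deescalation"] = _BOOL[value.lower()]
        elif key == "dose_probs":
            out["dose_probs"] = [float(v) for v in value.split(",") if v.strip()]
        else:
            out["conf_level"] = float(value)
    return out


def build_run_config(
    A: int,
    B: int,
    C: int,
    D: int,
    E: int,
    deescalation: bool,
    dose_probs: list[float],
    conf_level: float = 0.95,
    **kwargs,
) -> RunConfig:
    """Validate raw inputs into a :class:`RunConfig`."""
    design = validate_design(A, B, C, D, E, deescalation)
    scenario = ToxScenario(dose_probs)
    return RunConfig(design=design, scenario=scenario, conf_level=conf_level, **kwargs)
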