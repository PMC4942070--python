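"""Tables, plots and a rendered Markdown/HTML report for one run.

The artifact bundle mirrors the three output panes a trialist wants when
weighing up an A+B design: scenario plots (four bar charts), scenario
operating characteristics, and design operating characteristics
(terminal-MTD confidence intervals plus the tipping point).  Numbers in
the rendered report are formatted with the same rules as the exported
tables: percentages to 1 dp, probabilities and the tipping point to 3 dp,
rounding half away from zero.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .characteristics import design_characteristics_table, tipping_point
from .config import RunConfig
from .design import PathwaySet, enumerate_pathways
from .oc import ScenarioOCs, compute_scenario_ocs

__all__ = ["round_half_away", "run", "render_report"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (the convention used when
    comparing against published tables, where 0.45 prints as 0.5)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt_pct(x: float) -> str:
    return f"{round_half_away(x, 1):.1f}"


def _fmt_prob(x: float | None) -> str:
    return "-" if x is None else f"{round_half_away(x, 3):.3f}"


def _md_table(df: pd.DataFrame, formats: dict[str, str] | None = None) -> str:
    formats = formats or {}
    cols = list(df.columns)

    def cell(col: str, v) -> str:
        kind = formats.get(col)
        if kind == "pct":
            return _fmt_pct(float(v))
        if kind == "prob":
            return _fmt_prob(None if pd.isna(v) else float(v))
        return str(v)

    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(cell(c, row[c]) for c in cols) + " |")
    return "\n".join(lines)


def _scenario_plots(ocs: ScenarioOCs, out_dir: Path) -> list[Path]:
    paths = []
    specs = [
        ("sample_size_distribution.png", "Sample size distribution",
         [str(n) for n in ocs.sample_sizes.support], list(ocs.sample_sizes.probs),
         "total patients", "probability"),
        ("experimentation.png", "Experimentation percentages",
         [str(d.dose) for d in ocs.per_dose], [d.experimentation_pct for d in ocs.per_dose],
         "dose level", "% of patients"),
        ("mtd_recommendation.png", "MTD recommendation percentages",
         [str(d.dose) for d in ocs.per_dose] + ["none", "all tol."],
         [d.recommendation_pct for d in ocs.per_dose]
         + [ocs.prob_no_mtd_safety * 100.0, ocs.prob_all_tolerated * 100.0],
         "recommended MTD", "% of trials"),
        ("dlt_rate_distribution.png", "DLT rate distribution",
         [f"{float(r):.2f}" for r, _ in ocs.dlt_rates], [p for _, p in ocs.dlt_rates],
         "observed DLT rate", "probability"),
    ]
    for fname, title, labels, values, xlab, ylab in specs:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.bar(range(len(values)), values, color="#4477aa")
        ax.set_xticks(range(len(labels)))
        step = max(1, len(labels) // 12)  # thin crowded rate axes
        ax.set_xticklabels([l if i % step == 0 else "" for i, l in enumerate(labels)],
                           rotation=45 if len(labels) > 8 else 0, fontsize=7)
        ax.set_title(title)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def render_report(config: RunConfig, ps: PathwaySet, ocs: ScenarioOCs) -> str:
    """Render the full Markdown report for one (design, scenario) run."""
    design = config.design
    try:
        tp = tipping_point(design)
        tp_text = f"{round_half_away(tp.value, 3):.3f}"
    except ValueError:
        tp_text = "undefined (escalation certain for every DLT probability)"
    dct = design_characteristics_table(design, config.conf_level)

    per_dose = ocs.per_dose_table()
    lines = [
        "# A+B design evaluation",
        "",
        "## Design",
        "",
        f"- {design.name}",
        f"- Dose levels: {config.scenario.dose_count}; true DLT probabilities "
        + ", ".join(f"{p:g}" for p in config.scenario.dlt_probs),
        f"- Confidence level for MTD intervals: {config.conf_level:g}",
        f"- Distinct trial pathways: {len(ps)}",
        "",
        "## Scenario operating characteristics",
        "",
        _md_table(per_dose, {"true_dlt_prob": "prob", "experimentation_pct": "pct",
                             "recommendation_pct": "pct", "expected_patients": "prob",
                             "expected_dlts": "prob"}),
        "",
        f"- P(no MTD, too toxic): {_fmt_prob(ocs.prob_no_mtd_safety)}",
        f"- P(all doses tolerated): {_fmt_prob(ocs.prob_all_tolerated)}",
        f"- Expected toxicity level (ETL): {_fmt_prob(ocs.etl)}",
        f"- Expected overall toxicity rate (EOTR): {_fmt_prob(ocs.eotr)}",
        f"- Mean number of DLTs: {_fmt_prob(ocs.mean_dlts)}",
        f"- Expected sample size: {_fmt_prob(ocs.expected_sample_size)}",
        "",
        "### Summaries by true DLT probability interval",
        "",
        _md_table(ocs.interval_summaries,
                  {"experimentation_pct": "pct", "recommendation_pct": "pct"}),
        "",
        "## Design operating characteristics",
        "",
        f"Confidence intervals ({config.conf_level:g} level) for the DLT probability "
        "given the data that can be observed at the dose declared MTD:",
        "",
        _md_table(dct, {"estimate": "prob", "clopper_pearson_lower": "prob",
                        "clopper_pearson_upper": "prob", "wilson_lower": "prob",
                        "wilson_upper": "prob"}),
        "",
        f"- Tipping point: {tp_text}",
        "",
        "## Plots",
        "",
        "![Sample size distribution](sample_size_distribution.png)",
        "![Experimentation percentages](experimentation.png)",
        "![MTD recommendation percentages](mtd_recommendation.png)",
        "![DLT rate distribution](dlt_rate_distribution.png)",
        "",
    ]
    return "\n".join(lines)


def run(config: RunConfig) -> dict[str, Path]:
    """Evaluate the design and write the full artifact bundle.

    Returns a mapping from artifact name to written path.
    """
    out_dir = Path(config.out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not config.overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (pass overwrite to replace)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    ps = enumerate_pathways(config.design, config.scenario)
    ocs = compute_scenario_ocs(ps)

    written: dict[str, Path] = {}
    ps.to_csv(out_dir / "pathways.csv")
    ps.to_json(out_dir / "pathways.json")
    written["pathways_csv"] = out_dir / "pathways.csv"
    written["pathways_json"] = out_dir / "pathways.json"

    ocs.per_dose_table().to_csv(out_dir / "scenario_per_dose.csv", index=False)
    ocs.sample_sizes.to_dataframe().to_csv(out_dir / "sample_size_distribution.csv", index=False)
    ocs.interval_summaries.to_csv(out_dir / "interval_summaries.csv", index=False)
    ocs.to_json(out_dir / "scenario_ocs.json")
    written["scenario_per_dose_csv"] = out_dir / "scenario_per_dose.csv"
    written["scenario_ocs_json"] = out_dir / "scenario_ocs.json"

    dct = design_characteristics_table(config.design, config.conf_level)
    dct.to_csv(out_dir / "design_characteristics.csv", index=False)
    try:
        tp_value = tipping_point(config.design).value
    except ValueError:
        tp_value = None
    with open(out_dir / "design_characteristics.json", "w") as fh:
        json.dump({"tipping_point": tp_value,
                   "mtd_data_states": dct.to_dict(orient="records")}, fh, indent=1)
    written["design_characteristics_csv"] = out_dir / "design_characteristics.csv"
    written["design_characteristics_json"] = out_dir / "design_characteristics.json"

    for p in _scenario_plots(ocs, out_dir):
        written[p.stem + "_png"] = p

    body = render_report(config, ps, ocs)
    if config.report_format == "html":
        html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>A+B design evaluation</title></head><body><pre>\n"
            + body + "\n</pre></body></html>"
        )
        path = out_dir / "report.html"
        path.write_text(html)
    else:
        path = out_dir / "report.md"
        path.write_text(body)
    written["report"] = path
    return written
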