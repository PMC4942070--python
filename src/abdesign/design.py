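"""A+B dose-escalation designs and exact trial-pathway enumeration.

An A+B design treats successive cohorts of patients at increasing dose
levels.  At each dose a first cohort of ``A`` patients is observed; the
number of dose-limiting toxicities (DLTs) ``x`` determines what happens
next:

* ``x <= C - 1``      — escalate to the next dose,
* ``C <= x <= D``     — expand with a second cohort of ``B`` patients,
* ``x > D``           — stop escalating (halt, or begin de-escalation).

After expansion, the total DLT count ``y`` among all ``A + B`` patients at
the dose is compared with ``E``: escalate when ``y <= E``, otherwise halt /
de-escalate.  The classical 3+3 design is ``{A,B,C,D,E} = {3,3,1,1,1}``
without de-escalation.

Because every cohort outcome is a binomial draw with a dose-specific DLT
probability, a trial has finitely many possible realisations ("pathways"),
each with an exactly computable probability.  :func:`enumerate_pathways`
walks the full decision tree and returns every pathway together with its
probability and the maximum tolerated dose (MTD) the trial would declare.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "DesignSpec",
    "ToxScenario",
    "Phase",
    "Stage1Action",
    "Stage2Action",
    "OutcomeKind",
    "MTDOutcome",
    "CohortRecord",
    "TrialPathway",
    "PathwaySet",
    "validate_design",
    "stage1_decision",
    "stage2_decision",
    "determine_mtd",
    "pathway_probability",
    "enumerate_pathways",
]


class Stage1Action(Enum):
    """Decision after the first cohort of A patients at a dose."""

    ESCALATE = "escalate"
    EXPAND = "expand"
    HALT = "halt"


class Stage2Action(Enum):
    """Decision after the expanded cohort (A+B patients) at a dose."""

    ESCALATE = "escalate"
    HALT = "halt"


class Phase(Enum):
    """Whether a cohort was treated during escalation or de-escalation."""

    ESCALATION = "escalation"
    DEESCALATION = "deescalation"


class OutcomeKind(Enum):
    SELECTED = "selected"
    NONE_TOO_TOXIC = "none_too_toxic"
    ALL_TOLERATED = "all_tolerated"


@dataclass(frozen=True)
class MTDOutcome:
    """Terminal MTD declaration of a trial pathway.

    Exactly one of three cases applies: a dose level is selected as the
    MTD; every dose (including the lowest) proved too toxic; or the trial
    escalated past the highest planned dose with no dose ruled out.
    """

    kind: OutcomeKind
    dose: int | None = None

    def __post_init__(self) -> None:
        if self.kind is OutcomeKind.SELECTED:
            if self.dose is None or self.dose < 1:
                raise ValueError("SELECTED outcome requires a dose index >= 1")
        elif self.dose is not None:
            raise ValueError(f"{self.kind.name} outcome carries no dose index")

    @classmethod
    def selected(cls, dose: int) -> "MTDOutcome":
        return cls(OutcomeKind.SELECTED, dose)

    @classmethod
    def none_too_toxic(cls) -> "MTDOutcome":
        return cls(OutcomeKind.NONE_TOO_TOXIC)

    @classmethod
    def all_tolerated(cls) -> "MTDOutcome":
        return cls(OutcomeKind.ALL_TOLERATED)

    def label(self) -> str:
        if self.kind is OutcomeKind.SELECTED:
            return f"dose {self.dose}"
        return {"none_too_toxic": "no MTD (too toxic)",
                "all_tolerated": "all doses tolerated"}[self.kind.value]


@dataclass(frozen=True)
class DesignSpec:
    """The five rule integers plus de-escalation flag of an A+B design.

    Parameters
    ----------
    A : patients in the first cohort at each dose.
    B : patients in the second (expansion) cohort.
    C : minimum DLTs out of A needed to trigger expansion.
    D : maximum DLTs out of A allowed for expansion (``x > D`` halts).
    E : maximum DLTs out of A+B allowing escalation after expansion.
    allow_deescalation : whether excessive toxicity triggers stepping down
        through lower doses (expanding them to A+B patients) instead of
        stopping the trial outright.
    """

    A: int
    B: int
    C: int
    D: int
    E: int
    allow_deescalation: bool = False

    def __post_init__(self) -> None:
        for name in ("A", "B", "C", "D", "E"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise TypeError(f"design parameter {name} must be an integer, got {v!r}")
        if self.A < 1 or self.B < 1:
            raise ValueError(f"cohort sizes must be >= 1 (A={self.A}, B={self.B})")
        if not (1 <= self.C <= self.D <= self.A):
            raise ValueError(
                f"need 1 <= C <= D <= A, got C={self.C}, D={self.D}, A={self.A}"
            )
        if not (0 <= self.E <= self.A + self.B):
            raise ValueError(f"need 0 <= E <= A+B, got E={self.E}, A+B={self.A + self.B}")
        if self.E < self.C:
            warnings.warn(
                f"E={self.E} < C={self.C}: a dose that is expanded can never be "
                "escalated from",
                stacklevel=2,
            )
        elif self.E < self.D:
            warnings.warn(
                f"E={self.E} < D={self.D}: expansion after {self.D} DLTs can never "
                "lead to escalation",
                stacklevel=2,
            )

    @property
    def max_per_dose(self) -> int:
        return self.A + self.B

    @property
    def name(self) -> str:
        flag = "with" if self.allow_deescalation else "without"
        return (
            f"{self.A}+{self.B} design {{A,B,C,D,E}} = "
            f"{{{self.A},{self.B},{self.C},{self.D},{self.E}}} {flag} de-escalation"
        )


def validate_design(
    A: int, B: int, C: int, D: int, E: int, allow_deescalation: bool = False
) -> DesignSpec:
    """Validate the rule integers and return a :class:`DesignSpec`.

    Raises ``ValueError``/``TypeError`` on invariant violations and warns
    (without rejecting) on legal-but-odd configurations such as ``E < C``.
    """
    return DesignSpec(A, B, C, D, E, allow_deescalation)


@dataclass(frozen=True)
class ToxScenario:
    """Ordered true DLT probabilities for the planned dose levels."""

    dlt_probs: tuple[float, ...]

    def __init__(self, dlt_probs: Iterable[float]):
        probs = tuple(float(p) for p in dlt_probs)
        if len(probs) < 1:
            raise ValueError("scenario needs at least one dose level")
        for j, p in enumerate(probs, start=1):
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise ValueError(f"DLT probability at dose {j} must lie in [0,1], got {p}")
        if any(b < a for a, b in zip(probs, probs[1:])):
            warnings.warn("DLT probabilities are not monotone non-decreasing", stacklevel=2)
        object.__setattr__(self, "dlt_probs", probs)

    @property
    def dose_count(self) -> int:
        return len(self.dlt_probs)


@dataclass(frozen=True)
class CohortRecord:
    """One treated cohort: dose level, cohort size, DLT count, phase."""

    dose: int
    size: int
    dlts: int
    phase: Phase = Phase.ESCALATION

    def __post_init__(self) -> None:
        if self.dose < 1:
            raise ValueError("dose index is 1-based")
        if not (0 <= self.dlts <= self.size):
            raise ValueError(f"DLT count {self.dlts} outside 0..{self.size}")


@dataclass(frozen=True)
class TrialPathway:
    """One complete possible trial realisation.

    ``probability`` is the exact occurrence probability under the scenario
    the pathway was enumerated for (``None`` for simulated pathways, whose
    probability is implicit in the sampling).
    """

    cohorts: tuple[CohortRecord, ...]
    mtd: MTDOutcome
    probability: float | None
    n_total: int
    dlt_total: int
    patients_per_dose: tuple[int, ...]
    dlts_per_dose: tuple[int, ...]

    @classmethod
    def from_cohorts(
        cls,
        cohorts: Sequence[CohortRecord],
        mtd: MTDOutcome,
        dose_count: int,
        probability: float | None = None,
    ) -> "TrialPathway":
        npd = [0] * dose_count
        dpd = [0] * dose_count
        for c in cohorts:
            npd[c.dose - 1] += c.size
            dpd[c.dose - 1] += c.dlts
        return cls(
            cohorts=tuple(cohorts),
            mtd=mtd,
            probability=probability,
            n_total=sum(npd),
            dlt_total=sum(dpd),
            patients_per_dose=tuple(npd),
            dlts_per_dose=tuple(dpd),
        )

    def cohort_string(self) -> str:
        """Compact ``dose:size:dlts;...`` encoding of the cohort sequence."""
        return ";".join(f"{c.dose}:{c.size}:{c.dlts}" for c in self.cohorts)


@dataclass(frozen=True)
class PathwaySet:
    """The exhaustive, mutually exclusive pathway set for (design, scenario)."""

    design: DesignSpec
    scenario: ToxScenario
    pathways: tuple[TrialPathway, ...]

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def total_probability(self) -> float:
        return math.fsum(p.probability for p in self.pathways)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "pathway_id": i,
                "cohorts": pw.cohort_string(),
                "probability": pw.probability,
                "n_total": pw.n_total,
                "dlt_total": pw.dlt_total,
                "mtd_outcome": pw.mtd.kind.value,
                "mtd_dose": pw.mtd.dose if pw.mtd.dose is not None else "",
            }
            for i, pw in enumerate(self.pathways, start=1)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        records = self.to_dataframe().to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)


def stage1_decision(design: DesignSpec, x: int) -> Stage1Action:
    """Rule applied to the DLT count ``x`` among the first A patients."""
    if not (0 <= x <= design.A):
        raise ValueError(f"stage-1 DLT count {x} outside 0..{design.A}")
    if x <= design.C - 1:
        return Stage1Action.ESCALATE
    if x <= design.D:
        return Stage1Action.EXPAND
    return Stage1Action.HALT


def stage2_decision(design: DesignSpec, y: int) -> Stage2Action:
    """Rule applied to the total DLT count ``y`` among all A+B patients."""
    if not (design.C <= y <= design.A + design.B):
        raise ValueError(
            f"stage-2 total DLT count {y} outside {design.C}..{design.A + design.B}"
        )
    return Stage2Action.ESCALATE if y <= design.E else Stage2Action.HALT


def _binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def pathway_probability(pathway: TrialPathway, scenario: ToxScenario) -> float:
    """Exact occurrence probability: product of binomial cohort terms."""
    prob = 1.0
    for c in pathway.cohorts:
        prob *= _binom_pmf(c.dlts, c.size, scenario.dlt_probs[c.dose - 1])
    return prob


def determine_mtd(
    design: DesignSpec,
    halt_dose: int,
    patients_per_dose: Sequence[int],
    dlts_per_dose: Sequence[int],
    expansion_draw: Callable[[int, int], int] | None = None,
) -> tuple[MTDOutcome, list[CohortRecord]]:
    """Resolve the MTD after escalation halts at ``halt_dose``.

    Without de-escalation the dose below the halting dose is declared the
    MTD (or no MTD exists when the lowest dose halted).  With
    de-escalation the trial walks downward: each dose holding only A
    patients is expanded with a fresh cohort of B (outcome supplied by
    ``expansion_draw(dose, B) -> dlt_count``) and declared the MTD when its
    A+B-patient DLT total is at most E, otherwise the walk continues.

    Returns the outcome and any de-escalation cohorts appended on the way.
    Exhaustive enumeration branches over expansion outcomes itself and does
    not route through ``expansion_draw``.
    """
    if not design.allow_deescalation:
        if halt_dose > 1:
            return MTDOutcome.selected(halt_dose - 1), []
        return MTDOutcome.none_too_toxic(), []

    if expansion_draw is None:
        raise ValueError("de-escalation designs need an expansion_draw callable")
    n = list(patients_per_dose)
    d = list(dlts_per_dose)
    extra: list[CohortRecord] = []
    k = halt_dose - 1
    while k >= 1:
        if n[k - 1] == design.max_per_dose:
            if d[k - 1] <= design.E:
                return MTDOutcome.selected(k), extra
        else:
            dlts = expansion_draw(k, design.B)
            extra.append(CohortRecord(k, design.B, dlts, Phase.DEESCALATION))
            n[k - 1] += design.B
            d[k - 1] += dlts
            if d[k - 1] <= design.E:
                return MTDOutcome.selected(k), extra
        k -= 1
    return MTDOutcome.none_too_toxic(), extra


def enumerate_pathways(design: DesignSpec, scenario: ToxScenario) -> PathwaySet:
    """Exhaustively enumerate every possible trial pathway with its probability.

    The decision tree is walked depth-first from dose 1, branching over
    every binomial cohort outcome (no pruning, however improbable the
    branch), so the returned probabilities are exact and sum to one.
    """
    A, B, C, D, E = design.A, design.B, design.C, design.D, design.E
    J = scenario.dose_count
    p = scenario.dlt_probs
    pmf_a = [[_binom_pmf(x, A, pj) for x in range(A + 1)] for pj in p]
    pmf_b = [[_binom_pmf(y, B, pj) for y in range(B + 1)] for pj in p]

    out: list[TrialPathway] = []

    def finish(cohorts: list[CohortRecord], prob: float, mtd: MTDOutcome) -> None:
        out.append(TrialPathway.from_cohorts(cohorts, mtd, J, prob))

    def walk_down(k: int, cohorts, prob, n_per, d_per) -> None:
        # de-escalation: step down from dose k, expanding A-patient doses
        while k >= 1 and n_per[k - 1] == A + B:
            if d_per[k - 1] <= E:
                finish(cohorts, prob, MTDOutcome.selected(k))
                return
            k -= 1
        if k == 0:
            finish(cohorts, prob, MTDOutcome.none_too_toxic())
            return
        for y2 in range(B + 1):
            pr = prob * pmf_b[k - 1][y2]
            c2 = cohorts + [CohortRecord(k, B, y2, Phase.DEESCALATION)]
            total = d_per[k - 1] + y2
            if total <= E:
                finish(c2, pr, MTDOutcome.selected(k))
            else:
                n2 = list(n_per)
                d2 = list(d_per)
                n2[k - 1] += B
                d2[k - 1] = total
                walk_down(k - 1, c2, pr, n2, d2)

    def halt(j: int, cohorts, prob, n_per, d_per) -> None:
        if design.allow_deescalation:
            walk_down(j - 1, cohorts, prob, n_per, d_per)
        else:
            mtd, _ = determine_mtd(design, j, n_per, d_per)
            finish(cohorts, prob, mtd)

    def visit(j: int, cohorts, prob, n_per, d_per) -> None:
        for x in range(A + 1):
            prx = prob * pmf_a[j - 1][x]
            c1 = cohorts + [CohortRecord(j, A, x, Phase.ESCALATION)]
            n1 = list(n_per)
            d1 = list(d_per)
            n1[j - 1] += A
            d1[j - 1] += x
            action = stage1_decision(design, x)
            if action is Stage1Action.ESCALATE:
                if j == J:
                    finish(c1, prx, MTDOutcome.all_tolerated())
                else:
                    visit(j + 1, c1, prx, n1, d1)
            elif action is Stage1Action.EXPAND:
                for y2 in range(B + 1):
                    pry = prx * pmf_b[j - 1][y2]
                    c2 = c1 + [CohortRecord(j, B, y2, Phase.ESCALATION)]
                    n2 = list(n1)
                    d2 = list(d1)
                    n2[j - 1] += B
                    d2[j - 1] += y2
                    if stage2_decision(design, x + y2) is Stage2Action.ESCALATE:
                        if j == J:
                            finish(c2, pry, MTDOutcome.all_tolerated())
                        else:
                            visit(j + 1, c2, pry, n2, d2)
                    else:
                        halt(j, c2, pry, n2, d2)
            else:
                halt(j, c1, prx, n1, d1)

    visit(1, [], 1.0, [0] * J, [0] * J)
    return PathwaySet(design=design, scenario=scenario, pathways=tuple(out))
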