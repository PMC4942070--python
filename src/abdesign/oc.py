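"""Scenario-dependent operating characteristics of an A+B design.

All quantities here are exact expectations over the enumerated trial
pathway distribution.  Percentages that describe patient allocation
("experimentation") and toxicity burden (EOTR) are within-trial
proportions averaged over pathways, i.e. ``E[n_j / N]`` and
``E[DLTs / N]`` — not ratios of expectations, which is the approximation
older programs used and which systematically over-weights trials that
escalate far.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .design import OutcomeKind, PathwaySet, ToxScenario

__all__ = [
    "SampleSizeDistribution",
    "DoseOC",
    "ScenarioOCs",
    "TOX_BINS",
    "sample_size_distribution",
    "experimentation_percentages",
    "mtd_distribution",
    "expected_toxicity_level",
    "eotr",
    "mean_dlts",
    "dlt_rate_distribution",
    "interval_summaries",
    "compute_scenario_ocs",
]

#: Half-open true-DLT-probability bins used for interval summaries; the
#: first bin is closed on both sides, all others are (lo, hi].
TOX_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.2),
    (0.2, 0.4),
    (0.4, 0.6),
    (0.6, 0.8),
    (0.8, 1.0),
)


@dataclass(frozen=True)
class SampleSizeDistribution:
    """Exact distribution of the total trial sample size N."""

    support: tuple[int, ...]
    probs: tuple[float, ...]

    @property
    def mean(self) -> float:
        return math.fsum(n * p for n, p in zip(self.support, self.probs))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.support, "probability": self.probs})


@dataclass(frozen=True)
class DoseOC:
    """Per-dose summaries: allocation, recommendation, expected counts."""

    dose: int
    true_dlt_prob: float
    experimentation_pct: float
    recommendation_pct: float
    expected_patients: float
    expected_dlts: float


@dataclass(frozen=True)
class ScenarioOCs:
    """All exact scenario-dependent operating characteristics."""

    per_dose: tuple[DoseOC, ...]
    prob_no_mtd_safety: float
    prob_all_tolerated: float
    etl: float | None
    eotr: float
    mean_dlts: float
    expected_sample_size: float
    sample_sizes: SampleSizeDistribution
    dlt_rates: tuple[tuple[Fraction, float], ...]
    interval_summaries: pd.DataFrame

    def per_dose_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": [d.dose for d in self.per_dose],
                "true_dlt_prob": [d.true_dlt_prob for d in self.per_dose],
                "experimentation_pct": [d.experimentation_pct for d in self.per_dose],
                "recommendation_pct": [d.recommendation_pct for d in self.per_dose],
                "expected_patients": [d.expected_patients for d in self.per_dose],
                "expected_dlts": [d.expected_dlts for d in self.per_dose],
            }
        )

    def scalars(self) -> dict[str, float | None]:
        return {
            "prob_no_mtd_safety": self.prob_no_mtd_safety,
            "prob_all_tolerated": self.prob_all_tolerated,
            "etl": self.etl,
            "eotr": self.eotr,
            "mean_dlts": self.mean_dlts,
            "expected_sample_size": self.expected_sample_size,
        }

    def to_json(self, path) -> None:
        payload = {
            "per_dose": self.per_dose_table().to_dict(orient="records"),
            "scalars": self.scalars(),
            "sample_size_distribution": self.sample_sizes.to_dataframe().to_dict(
                orient="records"
            ),
            "dlt_rate_distribution": [
                {"rate": float(r), "dlts_over_n": f"{r.numerator}/{r.denominator}",
                 "probability": p}
                for r, p in self.dlt_rates
            ],
            "interval_summaries": self.interval_summaries.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def sample_size_distribution(ps: PathwaySet) -> SampleSizeDistribution:
    """Aggregate pathway probability by total sample size."""
    acc: dict[int, list[float]] = {}
    for pw in ps:
        acc.setdefault(pw.n_total, []).append(pw.probability)
    # degenerate scenarios (p_j exactly 0 or 1) enumerate impossible sizes
    totals = {n: math.fsum(v) for n, v in acc.items()}
    support = tuple(sorted(n for n, t in totals.items() if t > 0.0))
    return SampleSizeDistribution(
        support=support, probs=tuple(totals[n] for n in support)
    )


def experimentation_percentages(ps: PathwaySet) -> list[float]:
    """Exact expected within-trial percentage of patients treated per dose.

    For dose j this is ``100 * E[n_j / N]`` with the expectation taken over
    the pathway distribution; the percentages sum to 100 across doses.
    """
    J = ps.scenario.dose_count
    terms: list[list[float]] = [[] for _ in range(J)]
    for pw in ps:
        for j in range(J):
            if pw.patients_per_dose[j]:
                terms[j].append(pw.probability * pw.patients_per_dose[j] / pw.n_total)
    return [100.0 * math.fsum(t) for t in terms]


def mtd_distribution(
    ps: PathwaySet, all_tolerated: str = "separate"
) -> tuple[list[float], float, float]:
    """Per-dose MTD recommendation percentages plus the no-MTD categories.

    Returns ``(per_dose_pct, pct_none_too_toxic, pct_all_tolerated)``;
    the three parts sum to 100.  ``all_tolerated`` controls how trials
    that escalate past the highest planned dose are reported: kept as
    their own category (``"separate"``, the default), folded into
    selection of the top dose (``"top_dose"``), or folded into the no-MTD
    category (``"no_mtd"``).
    """
    if all_tolerated not in ("separate", "top_dose", "no_mtd"):
        raise ValueError(f"unknown all_tolerated convention {all_tolerated!r}")
    J = ps.scenario.dose_count
    sel: list[list[float]] = [[] for _ in range(J)]
    toxic: list[float] = []
    tolerated: list[float] = []
    for pw in ps:
        if pw.mtd.kind is OutcomeKind.SELECTED:
            sel[pw.mtd.dose - 1].append(pw.probability)
        elif pw.mtd.kind is OutcomeKind.NONE_TOO_TOXIC:
            toxic.append(pw.probability)
        else:
            tolerated.append(pw.probability)
    per_dose = [100.0 * math.fsum(s) for s in sel]
    pct_toxic = 100.0 * math.fsum(toxic)
    pct_tolerated = 100.0 * math.fsum(tolerated)
    if all_tolerated == "top_dose":
        per_dose[-1] += pct_tolerated
        pct_tolerated = 0.0
    elif all_tolerated == "no_mtd":
        pct_toxic += pct_tolerated
        pct_tolerated = 0.0
    return per_dose, pct_toxic, pct_tolerated


def expected_toxicity_level(ps: PathwaySet) -> float:
    """ETL: expected true DLT probability at the dose declared MTD.

    Conditional on the trial declaring an MTD.  A trial that escalates
    past the highest planned dose declares that top dose its MTD for this
    purpose; only trials that stop with every dose too toxic declare
    none.  Raises ``ValueError`` when no pathway declares an MTD (the
    quantity is then undefined).
    """
    top = ps.scenario.dose_count
    num: list[float] = []
    den: list[float] = []
    for pw in ps:
        if pw.mtd.kind is OutcomeKind.SELECTED:
            dose = pw.mtd.dose
        elif pw.mtd.kind is OutcomeKind.ALL_TOLERATED:
            dose = top
        else:
            continue
        num.append(pw.probability * ps.scenario.dlt_probs[dose - 1])
        den.append(pw.probability)
    total = math.fsum(den)
    if total <= 0.0:
        raise ValueError("ETL undefined: no pathway selects an MTD")
    return math.fsum(num) / total


def eotr(ps: PathwaySet) -> float:
    """Expected overall toxicity rate: ``E[total DLTs / N]`` over pathways."""
    return math.fsum(
        pw.probability * pw.dlt_total / pw.n_total for pw in ps
    )


def mean_dlts(ps: PathwaySet) -> float:
    """Expected number of DLTs in the whole trial."""
    return math.fsum(pw.probability * pw.dlt_total for pw in ps)


def dlt_rate_distribution(ps: PathwaySet) -> list[tuple[Fraction, float]]:
    """Exact distribution of the observed DLT rate (total DLTs / N).

    Rates are aggregated as exact rationals so pathways with equal rates
    (e.g. 1/6 and 2/12) pool correctly.
    """
    acc: dict[Fraction, list[float]] = {}
    for pw in ps:
        acc.setdefault(Fraction(pw.dlt_total, pw.n_total), []).append(pw.probability)
    totals = {r: math.fsum(v) for r, v in acc.items()}
    return [(r, totals[r]) for r in sorted(totals) if totals[r] > 0.0]


def _bin_index(p: float) -> int:
    if p <= TOX_BINS[0][1]:  # first bin is [0, 0.2], closed at zero
        return 0
    for i, (lo, hi) in enumerate(TOX_BINS[1:], start=1):
        if lo < p <= hi:
            return i
    return len(TOX_BINS) - 1


def interval_summaries(
    experimentation: list[float], recommendation: list[float], scenario: ToxScenario
) -> pd.DataFrame:
    """Sum per-dose percentages over true-DLT-probability bins.

    Bins are [0, 0.2], (0.2, 0.4], (0.4, 0.6], (0.6, 0.8], (0.8, 1]; a
    boundary probability belongs to the lower bin's closed right edge.
    """
    exp_sum = [0.0] * len(TOX_BINS)
    rec_sum = [0.0] * len(TOX_BINS)
    for j, p in enumerate(scenario.dlt_probs):
        i = _bin_index(p)
        exp_sum[i] += experimentation[j]
        rec_sum[i] += recommendation[j]
    labels = ["[0, 0.2]"] + [f"({lo}, {hi}]" for lo, hi in TOX_BINS[1:]]
    return pd.DataFrame(
        {
            "dlt_prob_interval": labels,
            "experimentation_pct": exp_sum,
            "recommendation_pct": rec_sum,
        }
    )


def compute_scenario_ocs(ps: PathwaySet) -> ScenarioOCs:
    """Compute every exact scenario operating characteristic at once."""
    J = ps.scenario.dose_count
    exp_pct = experimentation_percentages(ps)
    rec_pct, pct_toxic, pct_tolerated = mtd_distribution(ps)
    exp_patients = [
        math.fsum(pw.probability * pw.patients_per_dose[j] for pw in ps)
        for j in range(J)
    ]
    exp_dlts = [
        math.fsum(pw.probability * pw.dlts_per_dose[j] for pw in ps) for j in range(J)
    ]
    try:
        etl_val: float | None = expected_toxicity_level(ps)
    except ValueError:
        etl_val = None
    ssd = sample_size_distribution(ps)
    per_dose = tuple(
        DoseOC(
            dose=j + 1,
            true_dlt_prob=ps.scenario.dlt_probs[j],
            experimentation_pct=exp_pct[j],
            recommendation_pct=rec_pct[j],
            expected_patients=exp_patients[j],
            expected_dlts=exp_dlts[j],
        )
        for j in range(J)
    )
    return ScenarioOCs(
        per_dose=per_dose,
        prob_no_mtd_safety=pct_toxic / 100.0,
        prob_all_tolerated=pct_tolerated / 100.0,
        etl=etl_val,
        eotr=eotr(ps),
        mean_dlts=mean_dlts(ps),
        expected_sample_size=ssd.mean,
        sample_sizes=ssd,
        dlt_rates=tuple(dlt_rate_distribution(ps)),
        interval_summaries=interval_summaries(exp_pct, rec_pct, ps.scenario),
    )
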