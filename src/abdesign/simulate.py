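"""Monte-Carlo trial simulator: an independent check on the exact engine.

Each simulated trial draws cohort DLT counts from the binomial at the
current dose and applies the same decision functions
(:func:`~abdesign.design.stage1_decision`,
:func:`~abdesign.design.stage2_decision`,
:func:`~abdesign.design.determine_mtd`) as the exact enumerator, so any
systematic disagreement between empirical and exact operating
characteristics indicates a bug in one of the two routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    CohortRecord,
    DesignSpec,
    MTDOutcome,
    OutcomeKind,
    Phase,
    Stage1Action,
    Stage2Action,
    ToxScenario,
    TrialPathway,
    determine_mtd,
    stage1_decision,
    stage2_decision,
)
from .oc import ScenarioOCs

__all__ = ["SimulationConfig", "MCEstimates", "simulate_trial", "estimate_ocs", "comparison_table"]


@dataclass(frozen=True)
class SimulationConfig:
    design: DesignSpec
    scenario: ToxScenario
    n_sims: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


def simulate_trial(
    design: DesignSpec, scenario: ToxScenario, rng: np.random.Generator
) -> TrialPathway:
    """Simulate one complete trial; the probability field is left unset."""
    J = scenario.dose_count
    p = scenario.dlt_probs
    n_per = [0] * J
    d_per = [0] * J
    cohorts: list[CohortRecord] = []
    j = 1
    mtd: MTDOutcome | None = None
    while True:
        x = int(rng.binomial(design.A, p[j - 1]))
        cohorts.append(CohortRecord(j, design.A, x, Phase.ESCALATION))
        n_per[j - 1] += design.A
        d_per[j - 1] += x
        action = stage1_decision(design, x)
        if action is Stage1Action.EXPAND:
            y2 = int(rng.binomial(design.B, p[j - 1]))
            cohorts.append(CohortRecord(j, design.B, y2, Phase.ESCALATION))
            n_per[j - 1] += design.B
            d_per[j - 1] += y2
            action = (
                Stage1Action.ESCALATE
                if stage2_decision(design, x + y2) is Stage2Action.ESCALATE
                else Stage1Action.HALT
            )
        if action is Stage1Action.ESCALATE:
            if j == J:
                mtd = MTDOutcome.all_tolerated()
                break
            j += 1
            continue
        # halt: resolve MTD, possibly appending de-escalation cohorts
        mtd, extra = determine_mtd(
            design,
            j,
            n_per,
            d_per,
            expansion_draw=lambda dose, size: int(rng.binomial(size, p[dose - 1])),
        )
        cohorts.extend(extra)
        break
    return TrialPathway.from_cohorts(cohorts, mtd, J, probability=None)


@dataclass(frozen=True)
class MCEstimates:
    """Empirical operating characteristics with standard errors."""

    n_sims: int
    experimentation_pct: np.ndarray
    experimentation_se: np.ndarray
    recommendation_pct: np.ndarray
    recommendation_se: np.ndarray
    pct_no_mtd_safety: float
    pct_no_mtd_safety_se: float
    pct_all_tolerated: float
    pct_all_tolerated_se: float
    etl: float | None
    etl_se: float | None
    eotr: float
    eotr_se: float
    mean_dlts: float
    mean_dlts_se: float
    mean_sample_size: float
    mean_sample_size_se: float


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    m = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
    return m, se


def estimate_ocs(config: SimulationConfig) -> MCEstimates:
    """Empirical analogues of every exact operating characteristic."""
    design, scenario = config.design, config.scenario
    J = scenario.dose_count
    rng = np.random.default_rng(config.seed)
    n = config.n_sims

    frac = np.zeros((n, J))
    selected = np.zeros((n, J))
    toxic = np.zeros(n)
    tolerated = np.zeros(n)
    rates = np.zeros(n)
    dlts = np.zeros(n)
    sizes = np.zeros(n)
    etl_vals: list[float] = []

    for i in range(n):
        pw = simulate_trial(design, scenario, rng)
        frac[i] = np.asarray(pw.patients_per_dose) / pw.n_total
        if pw.mtd.kind is OutcomeKind.SELECTED:
            selected[i, pw.mtd.dose - 1] = 1.0
            etl_vals.append(scenario.dlt_probs[pw.mtd.dose - 1])
        elif pw.mtd.kind is OutcomeKind.NONE_TOO_TOXIC:
            toxic[i] = 1.0
        else:
            tolerated[i] = 1.0
            # an all-tolerated trial declares the top dose its MTD for ETL
            etl_vals.append(scenario.dlt_probs[-1])
        rates[i] = pw.dlt_total / pw.n_total
        dlts[i] = pw.dlt_total
        sizes[i] = pw.n_total

    exp_m = frac.mean(axis=0) * 100.0
    exp_se = frac.std(axis=0, ddof=1) / math.sqrt(n) * 100.0 if n > 1 else np.zeros(J)
    rec_m = selected.mean(axis=0) * 100.0
    rec_se = selected.std(axis=0, ddof=1) / math.sqrt(n) * 100.0 if n > 1 else np.zeros(J)
    tox_m, tox_se = _mean_se(toxic)
    tol_m, tol_se = _mean_se(tolerated)
    eotr_m, eotr_se = _mean_se(rates)
    dlt_m, dlt_se = _mean_se(dlts)
    size_m, size_se = _mean_se(sizes)
    if etl_vals:
        etl_m, etl_se = _mean_se(np.asarray(etl_vals))
    else:
        etl_m = etl_se = None

    return MCEstimates(
        n_sims=n,
        experimentation_pct=exp_m,
        experimentation_se=exp_se,
        recommendation_pct=rec_m,
        recommendation_se=rec_se,
        pct_no_mtd_safety=tox_m * 100.0,
        pct_no_mtd_safety_se=tox_se * 100.0,
        pct_all_tolerated=tol_m * 100.0,
        pct_all_tolerated_se=tol_se * 100.0,
        etl=etl_m,
        etl_se=etl_se,
        eotr=eotr_m,
        eotr_se=eotr_se,
        mean_dlts=dlt_m,
        mean_dlts_se=dlt_se,
        mean_sample_size=size_m,
        mean_sample_size_se=size_se,
    )


def comparison_table(exact: ScenarioOCs, mc: MCEstimates) -> pd.DataFrame:
    """Exact-vs-empirical table with z-scores (difference / SE)."""
    rows = []

    def add(name: str, ex: float | None, est: float | None, se: float | None) -> None:
        z = None
        if ex is not None and est is not None and se:
            z = (est - ex) / se
        rows.append({"quantity": name, "exact": ex, "mc_estimate": est, "mc_se": se, "z": z})

    for d in exact.per_dose:
        j = d.dose - 1
        add(f"experimentation_pct_dose_{d.dose}", d.experimentation_pct,
            float(mc.experimentation_pct[j]), float(mc.experimentation_se[j]))
    for d in exact.per_dose:
        j = d.dose - 1
        add(f"recommendation_pct_dose_{d.dose}", d.recommendation_pct,
            float(mc.recommendation_pct[j]), float(mc.recommendation_se[j]))
    add("pct_no_mtd_safety", exact.prob_no_mtd_safety * 100.0,
        mc.pct_no_mtd_safety, mc.pct_no_mtd_safety_se)
    add("pct_all_tolerated", exact.prob_all_tolerated * 100.0,
        mc.pct_all_tolerated, mc.pct_all_tolerated_se)
    add("etl", exact.etl, mc.etl, mc.etl_se)
    add("eotr", exact.eotr, mc.eotr, mc.eotr_se)
    add("mean_dlts", exact.mean_dlts, mc.mean_dlts, mc.mean_dlts_se)
    add("mean_sample_size", exact.expected_sample_size, mc.mean_sample_size,
        mc.mean_sample_size_se)
    return pd.DataFrame(rows)
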