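"""Scenario-independent properties of an A+B design.

These depend only on the rule integers, not on any dose-toxicity
scenario: the data states that can be observed at the dose declared MTD,
binomial confidence intervals for the DLT probability at that dose, the
escalation-probability curve, and its *tipping point* — the true DLT
probability at which a dose is equally likely to be escalated from as
not.  Doses above the tipping point are unlikely MTD candidates, which is
why the classical 3+3 (tipping point 0.297) tends to recommend doses with
true toxicity below 30% rather than the 33% folklore value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta, norm

from .design import DesignSpec

__all__ = [
    "MTDDataState",
    "CIMethod",
    "ConfidenceInterval",
    "TippingPoint",
    "mtd_data_states",
    "clopper_pearson_ci",
    "wilson_ci",
    "escalation_probability",
    "tipping_point",
    "design_characteristics_table",
]


@dataclass(frozen=True, order=True)
class MTDDataState:
    """Possible terminal data at the selected MTD: x DLTs out of n patients."""

    n: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.n):
            raise ValueError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")


class CIMethod(Enum):
    CLOPPER_PEARSON = "clopper_pearson"
    WILSON = "wilson"


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    method: CIMethod

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(f"malformed interval ({self.lower}, {self.upper})")


@dataclass(frozen=True)
class TippingPoint:
    value: float
    design: DesignSpec


def mtd_data_states(design: DesignSpec) -> list[MTDDataState]:
    """Enumerate the (x, n) data states observable at the selected MTD.

    Without de-escalation the MTD is a dose that was escalated from, so it
    holds either A patients with x <= C-1 DLTs or A+B patients whose total
    y passed the stage-2 check (y <= E, reachable from some stage-1 count
    in C..D).  With de-escalation every declared MTD has been expanded to
    A+B patients, with any total up to E.
    """
    A, B, C, D, E = design.A, design.B, design.C, design.D, design.E
    if design.allow_deescalation:
        return [MTDDataState(n=A + B, x=y) for y in range(E + 1)]
    states = [MTDDataState(n=A, x=x) for x in range(C)]
    for y in range(C, E + 1):
        # reachable iff some stage-1 count x in [C, D] satisfies y - x <= B
        if max(C, y - B) <= min(D, y):
            states.append(MTDDataState(n=A + B, x=y))
    return states


def _check_ci_args(x: int, n: int, level: float) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must lie in (0,1), got {level}")


def clopper_pearson_ci(x: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Exact (Clopper-Pearson) binomial confidence interval via beta quantiles.

    lower = Beta^{-1}(alpha/2; x, n-x+1), zero when x = 0;
    upper = Beta^{-1}(1-alpha/2; x+1, n-x), one when x = n.
    """
    _check_ci_args(x, n, level)
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return ConfidenceInterval(lower, upper, level, CIMethod.CLOPPER_PEARSON)


def wilson_ci(x: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    _check_ci_args(x, n, level)
    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    phat = x / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return ConfidenceInterval(
        max(0.0, centre - half), min(1.0, centre + half), level, CIMethod.WILSON
    )


def escalation_probability(design: DesignSpec, p: float) -> float:
    """Probability of escalating from a dose whose true DLT probability is p.

    Escalation happens either immediately (at most C-1 DLTs among the
    first A patients) or after expansion (stage-1 count x in C..D and at
    most E - x further DLTs among the B expansion patients).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0,1], got {p}")
    A, B, C, D, E = design.A, design.B, design.C, design.D, design.E

    # direct binomial terms: robust down to subnormal p, where scipy's
    # boost-backed pmf can overflow
    def pmf(k: int, n: int) -> float:
        return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)

    prob = sum(pmf(x, A) for x in range(C))
    for x in range(C, D + 1):
        if E - x >= 0:
            prob += pmf(x, A) * sum(pmf(y, B) for y in range(min(E - x, B) + 1))
    return prob


def tipping_point(design: DesignSpec, tol: float = 1e-8) -> TippingPoint:
    """Solve escalation_probability(p) = 1/2 for p on (0, 1).

    The curve is continuous, equals 1 at p = 0, and reaches 0 at p = 1
    whenever D < A or E < A+B; for boundary designs where it stays at 1
    everywhere no root exists and a ``ValueError`` is raised.
    """
    if design.D >= design.A and design.E >= design.A + design.B:
        raise ValueError(
            "tipping point undefined: escalation is certain for every p "
            f"(D={design.D} >= A={design.A} and E={design.E} >= A+B)"
        )
    root = brentq(lambda p: escalation_probability(design, p) - 0.5, 0.0, 1.0, xtol=tol)
    return TippingPoint(value=float(root), design=design)


def design_characteristics_table(
    design: DesignSpec, level: float = 0.95
) -> pd.DataFrame:
    """One row per terminal MTD data state with both CI methods."""
    rows = []
    for st in sorted(mtd_data_states(design)):
        cp = clopper_pearson_ci(st.x, st.n, level)
        wi = wilson_ci(st.x, st.n, level)
        rows.append(
            {
                "dlts": st.x,
                "patients": st.n,
                "estimate": st.x / st.n,
                "clopper_pearson_lower": cp.lower,
                "clopper_pearson_upper": cp.upper,
                "wilson_lower": wi.lower,
                "wilson_upper": wi.upper,
                "level": level,
            }
        )
    return pd.DataFrame(rows)
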