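"""Standardized effect sizes with confidence intervals, the four-case
significance/relevance classification, and design power calculations.

The standardized effect size (SES) of a treatment-vs-control comparison is
the difference in group means divided by the pooled SD (Cohen's d family),
computed over *experimental units* — here the cage means, never the
individual animals.  Its large-sample standard error is

    se(d)^2 = (n_C + n_T) / (n_C n_T) + d^2 / (2 (n_C + n_T - 2)),

and the 95 % interval d +/- z_0.975 se(d) is compared against zero
(statistical significance) and against relevance limits +/-L (default
L = 1.0 SD, the effect the trial was powered to detect):

    case a: not significant, CI inside (-L, L)      — clear negative
    case b: significant, CI not entirely beyond L   — significant, relevance unclear
    case c: significant, CI entirely beyond +/-L    — potentially relevant
    case d: not significant, CI not inside (-L, L)  — inconclusive

Boundary-touching intervals fall to the conservative cases b/d
("within" is open-interval containment, "outside" is strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateComparisonError, DomainError
from .trial_model import TrialDesign, group_summary

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class RelevanceLimits:
    """Symmetric biological-relevance limits +/-L on the SES scale."""

    limit: float = 1.0

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise DomainError("relevance limit must be positive")


DEFAULT_LIMITS = RelevanceLimits(1.0)


@dataclass(frozen=True)
class SESResult:
    endpoint: str
    gender: str
    time: float
    group: str
    d: float
    se_d: float
    ci_lo: float
    ci_hi: float
    n_control: int
    n_treatment: int
    case: str
    significant: bool
    relevant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class PowerResult:
    d: float
    n_per_group: int
    alpha: float
    two_sided: bool
    power: float


# ---------------------------------------------------------------------------
# Core estimator
# ---------------------------------------------------------------------------


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Pooled standard deviation sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2))."""
    if n1 < 2 or n2 < 2:
        raise DomainError("each group needs at least 2 units")
    if sd1 < 0 or sd2 < 0:
        raise DomainError("standard deviations must be non-negative")
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def hedges_factor(df: int) -> float:
    """Small-sample bias factor J(df) ~= 1 - 3/(4 df - 1) of the d estimator."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def classify_relevance(ci_lo: float, ci_hi: float, limits: RelevanceLimits = DEFAULT_LIMITS) -> str:
    """Classify a CI into case a/b/c/d (see module docstring)."""
    if ci_lo > ci_hi:
        raise DomainError("ci_lo must not exceed ci_hi")
    L = limits.limit
    significant = ci_lo > 0 or ci_hi < 0
    contained = ci_lo > -L and ci_hi < L
    outside = ci_lo > L or ci_hi < -L
    if significant:
        return "c" if outside else "b"
    return "a" if contained else "d"


def ses_estimate(
    mean_control: float,
    sd_control: float,
    n_control: int,
    mean_treatment: float,
    sd_treatment: float,
    n_treatment: int,
    *,
    endpoint: str = "",
    gender: str = "",
    time: float = float("nan"),
    group: str = "",
    limits: RelevanceLimits = DEFAULT_LIMITS,
    ci: str = "z",
    hedges: bool = False,
) -> SESResult:
    """SES of one treatment-vs-control comparison from group summaries.

    ``ci`` chooses the interval multiplier: the large-sample standard
    normal z (default) or the t quantile with n_C + n_T - 2 df.
    ``hedges=True`` applies the small-sample bias correction to d (off by
    default: the SES is defined as the plain mean difference over the
    pooled SD).

    A zero pooled SD with unequal means raises
    :class:`DegenerateComparisonError` (the standardized effect is
    unbounded); with equal means the comparison is returned as a flagged
    degenerate null result so batch runs complete.
    """
    sp = pooled_sd(sd_control, n_control, sd_treatment, n_treatment)
    nc, nt = n_control, n_treatment
    df = nc + nt - 2
    if sp == 0:
        if mean_treatment != mean_control:
            raise DegenerateComparisonError(
                f"zero pooled SD with unequal means for {endpoint!r}"
            )
        return SESResult(endpoint, gender, time, group, 0.0, float("nan"),
                         0.0, 0.0, nc, nt, "a", False, False, degenerate=True)
    d = (mean_treatment - mean_control) / sp
    if hedges:
        d *= hedges_factor(df)
    se = math.sqrt((nc + nt) / (nc * nt) + d**2 / (2 * df))
    mult = Z975 if ci == "z" else float(stats.t.ppf(0.975, df))
    lo, hi = d - mult * se, d + mult * se
    case = classify_relevance(lo, hi, limits)
    return SESResult(
        endpoint, gender, time, group, d, se, lo, hi, nc, nt,
        case, case in ("b", "c"), case == "c",
    )


def ses_batch(
    cage_table: pd.DataFrame,
    design: TrialDesign,
    limits: RelevanceLimits = DEFAULT_LIMITS,
    ci: str = "z",
    hedges: bool = False,
) -> list[SESResult]:
    """One SES comparison per (gender, endpoint, time, treatment group) of a
    cage-aggregated table, each treatment compared against the control.

    Groups with fewer than 2 cages at a time point are skipped with a
    warning.  Zero-variance cells yield flagged degenerate results.
    Deterministic ordering: gender, endpoint, time, then design group
    order.
    """
    summ = group_summary(cage_table)
    order = {g: i for i, g in enumerate(design.groups)}
    results: list[SESResult] = []
    cells = summ.groupby(["gender", "endpoint", "time"], sort=True)
    for (gender, endpoint, time), cell in cells:
        cell = cell.set_index("group")
        if design.control not in cell.index:
            logger.warning("no control data for %s/%s/t=%s", gender, endpoint, time)
            continue
        ctrl = cell.loc[design.control]
        for grp in sorted(set(cell.index) - {design.control}, key=lambda g: order.get(g, 99)):
            trt = cell.loc[grp]
            if ctrl["n"] < 2 or trt["n"] < 2:
                logger.warning("skipping %s vs control for %s/%s/t=%s: <2 cages",
                               grp, gender, endpoint, time)
                continue
            try:
                res = ses_estimate(
                    ctrl["mean"], ctrl["sd"], int(ctrl["n"]),
                    trt["mean"], trt["sd"], int(trt["n"]),
                    endpoint=endpoint, gender=gender, time=time, group=grp,
                    limits=limits, ci=ci, hedges=hedges,
                )
            except DegenerateComparisonError:
                res = SESResult(endpoint, gender, time, grp, float("inf"),
                                float("nan"), float("nan"), float("nan"),
                                int(ctrl["n"]), int(trt["n"]), "d",
                                False, False, degenerate=True)
            results.append(res)
    return results


def results_to_frame(results: list[SESResult]) -> pd.DataFrame:
    """SES results as a DataFrame with a fixed column order."""
    cols = ["gender", "endpoint", "time", "group", "d", "se_d", "ci_lo", "ci_hi",
            "n_control", "n_treatment", "case", "significant", "relevant", "degenerate"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


# ---------------------------------------------------------------------------
# Power and sample size
# ---------------------------------------------------------------------------


def ses_power(d: float, n_per_group: int, alpha: float = 0.05, two_sided: bool = True) -> PowerResult:
    """Power of the pooled-variance two-sample t-test for standardized
    effect ``d`` with ``n_per_group`` experimental units per group,
    computed from the noncentral t distribution with 2n-2 df and
    noncentrality d sqrt(n/2)."""
    if n_per_group < 2:
        raise DomainError("n_per_group must be at least 2")
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    if two_sided:
        crit = stats.t.ppf(1 - alpha / 2, df)
        power = stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)
    else:
        crit = stats.t.ppf(1 - alpha, df)
        power = stats.nct.sf(crit, df, nc)
    return PowerResult(d, n_per_group, alpha, two_sided, float(power))


def required_n(
    d: float,
    target_power: float = 0.85,
    alpha: float = 0.05,
    two_sided: bool = True,
    n_max: int = 100_000,
) -> int:
    """Smallest n per group with power >= ``target_power`` at effect ``d``."""
    if d == 0:
        raise DomainError("effect size must be nonzero")
    if not 0 < target_power < 1:
        raise DomainError("target power must be in (0, 1)")
    lo, hi = 2, 2
    while ses_power(d, hi, alpha, two_sided).power < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise DomainError(f"power {target_power} unreachable below n = {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if ses_power(d, mid, alpha, two_sided).power >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi
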