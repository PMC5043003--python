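"""Decision-tree "classical" testing of endpoint cells.

For every (endpoint, gender, time) cell of the cage-aggregated table the
assumption gates are checked first — Kolmogorov–Smirnov normality with the
Lilliefors correction (mean and SD estimated from the sample; the null
distribution of the statistic is obtained by seeded Monte-Carlo
simulation) on the pooled ANOVA residuals, and Levene's test for variance
homogeneity.  If both pass, the parametric branch runs a one-way ANOVA
with Dunnett's many-to-one comparisons and unadjusted post hoc t tests
against control; otherwise (and always for qualitative-ordinal endpoints)
the nonparametric branch runs Kruskal–Wallis with pairwise Wilcoxon
rank-sum tests against control.  Post hoc flags are gated on omnibus
significance on the decision-tree path; the three fixed single-method
analyses used for cross-method comparison are ungated.

Dunnett's adjusted p-values are evaluated by numerical integration over
the control-variate representation of the max-|T| distribution: writing
the group means as mu + sigma Z_i / sqrt(n_i) and the pooled SD as
sigma U with nu U^2 ~ chi^2_nu,

    P(max_i |T_i| <= t) = E_{U, Z_0} prod_i [ Phi(b_i) - Phi(a_i) ],
    a_i, b_i = sqrt(n_i) ( Z_0/sqrt(n_0) -/+ t U w_i ),
    w_i = sqrt(1/n_i + 1/n_0),

integrated with Gauss–Hermite nodes in Z_0 and Gauss–Legendre nodes in U
over its truncated chi density (accuracy ~1e-6, well inside the 1e-4
target).  A seeded Monte-Carlo fallback handles more than 16 treatment
groups.

Degenerate zero-variance cells never raise: ANOVA-type statistics with
zero within-group variance and unequal means return the capped statistic
``F_CAP`` with p = 0 and a degeneracy flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .trial_model import TrialDesign

#: Capped statistic reported when zero within-group variance meets unequal
#: means (infinite evidence against the null at any finite precision).
F_CAP = 1e12

#: Default seed of the Lilliefors Monte-Carlo null (fixed for determinism).
LILLIEFORS_SEED = 987654321


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: object = None
    alpha: float = 0.05
    exact: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise DomainError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ClassicalResult:
    endpoint: str
    gender: str
    time: float
    path: str  # "parametric" | "nonparametric"
    normality: TestResult | None
    homogeneity: TestResult | None
    omnibus: TestResult
    flags: Mapping[str, Mapping[str, bool]]  # group -> {method: flag}
    alpha: float = 0.05

    def significant(self, group: str) -> bool:
        """Decision-tree significance of one comparison: Dunnett on the
        parametric path, Wilcoxon on the nonparametric path."""
        key = "dunnett" if self.path == "parametric" else "wilcoxon"
        return bool(self.flags[group][key])


# ---------------------------------------------------------------------------
# Normality: Kolmogorov-Smirnov with Lilliefors correction
# ---------------------------------------------------------------------------


def lilliefors_statistic(values: np.ndarray) -> float:
    """KS distance between the empirical CDF and a normal with estimated
    mean and SD (studentization makes it location/scale invariant)."""
    x = np.sort(np.asarray(values, float))
    n = x.size
    s = x.std(ddof=1)
    if s == 0:
        return 1.0  # degenerate sample: maximal distance
    cdf = stats.norm.cdf((x - x.mean()) / s)
    i = np.arange(1, n + 1)
    return float(max(np.max(i / n - cdf), np.max(cdf - (i - 1) / n)))


_LILLIEFORS_NULL: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_null(n: int, n_sim: int, seed: int) -> np.ndarray:
    key = (n, n_sim, seed)
    if key not in _LILLIEFORS_NULL:
        rng = np.random.default_rng(seed)
        x = np.sort(rng.standard_normal((n_sim, n)), axis=1)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        cdf = stats.norm.cdf(z)
        i = np.arange(1, n + 1)
        d = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
        _LILLIEFORS_NULL[key] = np.sort(d)
    return _LILLIEFORS_NULL[key]


def lilliefors_normality(
    values: Sequence[float],
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int = LILLIEFORS_SEED,
) -> TestResult:
    """Lilliefors-corrected KS normality test with a Monte-Carlo p-value
    (``(1 + #{D_null >= D}) / (n_sim + 1)``); the simulated null is cached
    per sample size."""
    x = np.asarray(list(values), float)
    if x.size < 5:
        raise DomainError("Lilliefors test needs at least 5 values")
    d = lilliefors_statistic(x)
    null = _lilliefors_null(x.size, n_sim, seed)
    n_ge = null.size - np.searchsorted(null, d, side="left")
    p = (1.0 + n_ge) / (n_sim + 1.0)
    return TestResult("lilliefors", d, float(p), df=x.size, alpha=alpha)


# ---------------------------------------------------------------------------
# ANOVA machinery (from raw values or printed summary statistics)
# ---------------------------------------------------------------------------


def anova_from_summary(ns: Sequence[int], means: Sequence[float], sds: Sequence[float]) -> TestResult:
    """One-way ANOVA F from per-group (n, mean, sd) summaries alone."""
    ns = np.asarray(ns, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    k = ns.size
    if k < 2 or np.any(ns < 2):
        raise DomainError("ANOVA needs >= 2 groups with >= 2 units each")
    n_tot = ns.sum()
    grand = float((ns * means).sum() / n_tot)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, int(n_tot - k)
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0.0:
        if msb == 0.0:
            return TestResult("anova", 0.0, 1.0, df=(df_b, df_w), degenerate=True)
        return TestResult("anova", F_CAP, 0.0, df=(df_b, df_w), degenerate=True)
    f = msb / msw
    return TestResult("anova", f, float(stats.f.sf(f, df_b, df_w)), df=(df_b, df_w))


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA on raw group values (delegates to the summary form,
    which it must equal by construction)."""
    arrs = [np.asarray(list(g), float) for g in groups]
    return anova_from_summary(
        [a.size for a in arrs],
        [a.mean() for a in arrs],
        [a.std(ddof=1) for a in arrs],
    )


def levene_test(groups: Sequence[Sequence[float]], center: str = "mean") -> TestResult:
    """Levene's homogeneity-of-variance test: one-way ANOVA F on absolute
    deviations from the group center (``mean`` = classic Levene,
    ``median`` = Brown-Forsythe)."""
    if center not in ("mean", "median"):
        raise DomainError(f"unknown center {center!r}")
    arrs = [np.asarray(list(g), float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise DomainError("Levene test needs >= 2 groups with >= 2 values each")
    devs = [
        np.abs(a - (a.mean() if center == "mean" else np.median(a))) for a in arrs
    ]
    res = one_way_anova(devs)
    return TestResult(f"levene_{center}", res.statistic, res.p_value,
                      df=res.df, degenerate=res.degenerate)


def _pooled_mse(arrs: Sequence[np.ndarray]) -> tuple[float, int]:
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df = sum(a.size for a in arrs) - len(arrs)
    return float(ssw) / df, df


def posthoc_t(
    control_values: Sequence[float],
    treatment_value_lists: Sequence[Sequence[float]],
    two_sided: bool = True,
) -> list[TestResult]:
    """Unadjusted pairwise t tests of each treatment against control using
    the pooled ANOVA MSE with df = N - k."""
    ctrl = np.asarray(list(control_values), float)
    trts = [np.asarray(list(t), float) for t in treatment_value_lists]
    mse, df = _pooled_mse([ctrl] + trts)
    out = []
    for t in trts:
        se2 = mse * (1.0 / t.size + 1.0 / ctrl.size)
        if se2 == 0.0:
            stat = 0.0 if t.mean() == ctrl.mean() else F_CAP
            p = 1.0 if stat == 0.0 else 0.0
            out.append(TestResult("posthoc_t", stat, p, df=df, degenerate=True))
            continue
        stat = (t.mean() - ctrl.mean()) / math.sqrt(se2)
        p = 2 * stats.t.sf(abs(stat), df) if two_sided else stats.t.sf(stat, df)
        out.append(TestResult("posthoc_t", float(stat), float(p), df=df))
    return out


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

_GH_NODES = 80
_GL_NODES = 128


def _quad_grids(df: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    z, wz = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    wz = wz / math.sqrt(2 * math.pi)
    # U = S/sigma with nu U^2 ~ chi^2_nu; integrate over its truncated support
    lo = math.sqrt(stats.chi2.ppf(1e-10, df) / df)
    hi = math.sqrt(stats.chi2.isf(1e-10, df) / df)
    x, wx = np.polynomial.legendre.leggauss(_GL_NODES)
    u = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    dens = (
        2.0
        * np.exp(
            (df / 2.0) * math.log(df / 2.0)
            - math.lgamma(df / 2.0)
            + (df - 1) * np.log(u)
            - df * u**2 / 2.0
        )
    )
    wu = 0.5 * (hi - lo) * wx * dens
    return z, wz, u, wu


def dunnett_max_t_cdf(
    t: float,
    n_treat: Sequence[int],
    n_control: int,
    df: int,
    two_sided: bool = True,
) -> float:
    """P(max_i |T_i| <= t) (or max T_i, one-sided) for the joint Dunnett
    statistics with treatment sizes ``n_treat`` and control size
    ``n_control``, by control-variate quadrature."""
    if t <= 0:
        return 0.0
    ns = np.asarray(n_treat, float)
    z, wz, u, wu = _quad_grids(df)
    w = np.sqrt(1.0 / ns + 1.0 / n_control)  # (k,)
    center = np.sqrt(ns)[None, None, :] * (z[None, :, None] / math.sqrt(n_control))
    half = np.sqrt(ns)[None, None, :] * (t * u[:, None, None] * w[None, None, :])
    upper = stats.norm.cdf(center + half)
    if two_sided:
        lower = stats.norm.cdf(center - half)
        probs = np.prod(upper - lower, axis=2)
    else:
        probs = np.prod(upper, axis=2)
    return float(wu @ probs @ wz)


def _dunnett_mc_cdf(
    t: float, n_treat: Sequence[int], n_control: int, df: int,
    two_sided: bool, n_draw: int = 200_000, seed: int = 20240517,
) -> float:
    rng = np.random.default_rng(seed)
    ns = np.asarray(n_treat, float)
    z0 = rng.standard_normal(n_draw)
    zi = rng.standard_normal((n_draw, ns.size))
    u = np.sqrt(rng.chisquare(df, n_draw) / df)
    w = np.sqrt(1.0 / ns + 1.0 / n_control)
    ts = (zi / np.sqrt(ns) - z0[:, None] / math.sqrt(n_control)) / (u[:, None] * w)
    stat = np.abs(ts).max(axis=1) if two_sided else ts.max(axis=1)
    return float(np.mean(stat <= t))


def dunnett_test(
    control_values: Sequence[float],
    treatment_value_lists: Sequence[Sequence[float]],
    two_sided: bool = True,
) -> list[TestResult]:
    """Dunnett many-to-one comparisons of each treatment mean against the
    control mean under the homogeneous-variance model; returns one
    adjusted p-value per treatment."""
    ctrl = np.asarray(list(control_values), float)
    trts = [np.asarray(list(t), float) for t in treatment_value_lists]
    if ctrl.size < 2 or any(t.size < 2 for t in trts):
        raise DomainError("Dunnett test needs >= 2 values per group")
    mse, df = _pooled_mse([ctrl] + trts)
    ns = [t.size for t in trts]
    cdf = dunnett_max_t_cdf if len(trts) <= 16 else _dunnett_mc_cdf
    out = []
    for t in trts:
        se2 = mse * (1.0 / t.size + 1.0 / ctrl.size)
        if se2 == 0.0:
            stat = 0.0 if t.mean() == ctrl.mean() else F_CAP
            p = 1.0 if stat == 0.0 else 0.0
            out.append(TestResult("dunnett", stat, p, df=df, degenerate=True))
            continue
        stat = (t.mean() - ctrl.mean()) / math.sqrt(se2)
        ref = abs(stat) if two_sided else stat
        p = 1.0 - cdf(ref, ns, ctrl.size, df, two_sided)
        out.append(TestResult("dunnett", float(stat), float(min(max(p, 0.0), 1.0)), df=df))
    return out


# ---------------------------------------------------------------------------
# Nonparametric branch
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square p (df = k-1);
    fully tied data give H = 0, p = 1."""
    arrs = [np.asarray(list(g), float) for g in groups]
    if len(arrs) < 2 or any(a.size < 1 for a in arrs):
        raise DomainError("Kruskal-Wallis needs >= 2 non-empty groups")
    k = len(arrs)
    if np.unique(np.concatenate(arrs)).size == 1:
        return TestResult("kruskal_wallis", 0.0, 1.0, df=k - 1, degenerate=True)
    h, p = stats.kruskal(*arrs)
    return TestResult("kruskal_wallis", float(h), float(p), df=k - 1)


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float], two_sided: bool = True) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    Exact p by enumeration for n_a + n_b <= 20 without ties; normal
    approximation with tie and continuity correction otherwise.  The most
    central configuration (U at its null mean, e.g. identical samples)
    reports p = 1 exactly.
    """
    x = np.asarray(list(a), float)
    y = np.asarray(list(b), float)
    if x.size == 0 or y.size == 0:
        raise DomainError("empty sample")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size + y.size <= 20) and not ties
    alternative = "two-sided" if two_sided else "greater"
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult("wilcoxon", x.size * y.size / 2.0, 1.0, exact=False, degenerate=True)
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u, p = float(res.statistic), float(res.pvalue)
    if two_sided and u == x.size * y.size / 2.0:
        p = 1.0
    return TestResult("wilcoxon", u, min(p, 1.0), exact=exact)


# ---------------------------------------------------------------------------
# Decision tree and batch drivers
# ---------------------------------------------------------------------------


def _cell_groups(cell: pd.DataFrame, design: TrialDesign) -> tuple[list[str], list[np.ndarray]]:
    order = [g for g in design.groups if g in set(cell["group"])]
    return order, [cell.loc[cell["group"] == g, "value"].to_numpy(float) for g in order]


def decision_tree_analyze(
    cell: pd.DataFrame,
    design: TrialDesign,
    alpha: float = 0.05,
    levene_center: str = "mean",
    gate: bool = True,
    normality_on: str = "residuals",
    all_methods: bool = False,
) -> ClassicalResult:
    """Analyse one (endpoint, gender, time) cell of the cage table along the
    decision tree.

    Quantitative cells are gated on Lilliefors normality (of the pooled
    ANOVA residuals by default, per group if ``normality_on='groups'``) and
    Levene homogeneity at ``alpha``; qualitative-ordinal cells (and
    zero-variance degenerate cells) go straight to the nonparametric
    branch.  Post hoc flags are set on the taken path only, unless
    ``all_methods`` is true; ``gate=False`` sets them regardless of the
    omnibus p.
    """
    endpoint = str(cell["endpoint"].iloc[0])
    gender = str(cell["gender"].iloc[0])
    time = float(cell["time"].iloc[0])
    kind = str(cell["kind"].iloc[0]) if "kind" in cell.columns else "quantitative"
    labels, groups = _cell_groups(cell, design)
    if design.control not in labels:
        raise DomainError(f"no control group in cell {endpoint}/{gender}/t={time}")
    if any(g.size < 2 for g in groups):
        raise DomainError("decision tree needs >= 2 cages per group")
    ctrl = groups[labels.index(design.control)]
    trt_labels = [l for l in labels if l != design.control]
    trts = [groups[labels.index(l)] for l in trt_labels]

    normality = homogeneity = None
    degenerate = all(np.ptp(g) == 0 for g in groups)
    if kind == "quantitative" and not degenerate:
        if normality_on == "residuals":
            resid = np.concatenate([g - g.mean() for g in groups])
            normality = lilliefors_normality(resid, alpha=alpha)
        else:
            ps = [lilliefors_normality(g, alpha=alpha) for g in groups]
            worst = min(ps, key=lambda r: r.p_value)
            normality = worst
        homogeneity = levene_test(groups, center=levene_center)
        parametric = normality.p_value >= alpha and homogeneity.p_value >= alpha
    else:
        parametric = False

    flags: dict[str, dict[str, bool]] = {l: {} for l in trt_labels}
    if parametric or all_methods:
        omnibus_par = one_way_anova(groups)
        run_post = (not gate) or omnibus_par.p_value < alpha
        dn = dunnett_test(ctrl, trts)
        tt = posthoc_t(ctrl, trts)
        for l, d_res, t_res in zip(trt_labels, dn, tt):
            flags[l]["dunnett"] = bool(run_post and d_res.p_value < alpha)
            flags[l]["posthoc_t"] = bool(run_post and t_res.p_value < alpha)
    if (not parametric) or all_methods:
        omnibus_np = kruskal_wallis(groups)
        run_post = (not gate) or omnibus_np.p_value < alpha
        for l, t in zip(trt_labels, trts):
            w = wilcoxon_ranksum(t, ctrl)
            flags[l]["wilcoxon"] = bool(run_post and w.p_value < alpha)

    omnibus = omnibus_par if parametric else omnibus_np
    if not all_methods:
        # only the taken path's flags are reported
        key = ("dunnett", "posthoc_t") if parametric else ("wilcoxon",)
        flags = {l: {k: v for k, v in f.items() if k in key} for l, f in flags.items()}
    return ClassicalResult(
        endpoint, gender, time,
        "parametric" if parametric else "nonparametric",
        normality, homogeneity, omnibus, flags, alpha,
    )


def classical_batch(
    cage_table: pd.DataFrame,
    design: TrialDesign,
    alpha: float = 0.05,
    **kwargs,
) -> list[ClassicalResult]:
    """Decision-tree analysis of every (gender, endpoint, time) cell."""
    out = []
    for _, cell in cage_table.groupby(["gender", "endpoint", "time"], sort=True):
        counts = cell.groupby("group")["value"].size()
        if (counts < 2).any() or design.control not in counts.index:
            continue
        out.append(decision_tree_analyze(cell, design, alpha=alpha, **kwargs))
    return out


def classical_flags(results: Sequence[ClassicalResult], design: TrialDesign) -> pd.Series:
    """Decision-tree significance per comparison as a boolean Series indexed
    by (gender, endpoint, time, group)."""
    idx, vals = [], []
    for r in results:
        for g in design.treatment_groups:
            if g in r.flags:
                idx.append((r.gender, r.endpoint, r.time, g))
                vals.append(r.significant(g))
    index = pd.MultiIndex.from_tuples(idx, names=["gender", "endpoint", "time", "group"])
    return pd.Series(vals, index=index, name="significant").sort_index()


def classical_to_frame(results: Sequence[ClassicalResult], design: TrialDesign) -> pd.DataFrame:
    """One row per comparison with the path and assumption p-values."""
    rows = []
    for r in results:
        for g, f in r.flags.items():
            rows.append(
                {
                    "gender": r.gender, "endpoint": r.endpoint, "time": r.time,
                    "group": g, "path": r.path,
                    "normality_p": r.normality.p_value if r.normality else float("nan"),
                    "homogeneity_p": r.homogeneity.p_value if r.homogeneity else float("nan"),
                    "omnibus_p": r.omnibus.p_value,
                    "significant": r.significant(g),
                    **{f"flag_{k}": v for k, v in f.items()},
                }
            )
    return pd.DataFrame(rows).sort_values(["gender", "endpoint", "time", "group"]).reset_index(drop=True)


SINGLE_METHODS = ("anova_t", "anova_dunnett", "kw_wilcoxon")


def run_single_method(
    cage_table: pd.DataFrame,
    method: str,
    design: TrialDesign,
    alpha: float = 0.05,
) -> pd.Series:
    """Apply one fixed test battery to every comparison, ungated: boolean
    flag per (gender, endpoint, time, treatment group) at ``alpha``."""
    if method not in SINGLE_METHODS:
        raise DomainError(f"unknown method {method!r}; choose from {SINGLE_METHODS}")
    idx, vals = [], []
    for (gender, endpoint, time), cell in cage_table.groupby(
        ["gender", "endpoint", "time"], sort=True
    ):
        counts = cell.groupby("group")["value"].size()
        if (counts < 2).any() or design.control not in counts.index:
            continue
        labels, groups = _cell_groups(cell, design)
        ctrl = groups[labels.index(design.control)]
        trt_labels = [l for l in labels if l != design.control]
        trts = [groups[labels.index(l)] for l in trt_labels]
        if method == "anova_t":
            ps = [r.p_value for r in posthoc_t(ctrl, trts)]
        elif method == "anova_dunnett":
            ps = [r.p_value for r in dunnett_test(ctrl, trts)]
        else:
            ps = [wilcoxon_ranksum(t, ctrl).p_value for t in trts]
        for l, p in zip(trt_labels, ps):
            idx.append((gender, endpoint, time, l))
            vals.append(bool(p < alpha))
    index = pd.MultiIndex.from_tuples(idx, names=["gender", "endpoint", "time", "group"])
    return pd.Series(vals, index=index, name=method).sort_index()
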