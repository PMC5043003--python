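"""Growth-curve and repeated-measures analysis by AR(1) generalized least
squares with REML estimation.

The model for a cage-level longitudinal series (body weight, feed
consumption, feed efficiency) is

    y_ct = beta_0 + beta_g 1[group g] + beta_w * week (+ group x week) + e_ct,

with the residuals of one cage following a continuous-lag AR(1) process:
corr(e_ct, e_ct') = rho^{|t - t'|} in weeks, so the weekly-then-biweekly
recording schedule is handled exactly.  Because the AR(1) process is
Markov, each cage's series can be whitened sequentially,

    e*_1 = e_1,   e*_j = (e_j - r_j e_{j-1}) / sqrt(1 - r_j^2),
    r_j = rho^{t_j - t_{j-1}},

which turns GLS into OLS on the starred data and gives the correlation
log-determinant in closed form (sum of log(1 - r_j^2)).  The REML
criterion is profiled over rho by bounded scalar search on (-0.99, 0.99)
(restricted to [0, 0.99) if the time grid has non-integer gaps, where a
negative rho has no continuous-lag meaning); sigma^2 and beta have closed
forms at each rho.  Contrast p-values use the t distribution with N - p
residual degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError, RankError
from .trial_model import TrialDesign

logger = logging.getLogger(__name__)

RHO_BOUND = 0.99


@dataclass
class LongitudinalFit:
    params: pd.Series
    cov_params: pd.DataFrame
    rho: float
    sigma2: float
    reml_loglik: float
    df_resid: int
    contrasts: pd.DataFrame  # group offsets vs control
    converged: bool
    control: str
    groups: tuple[str, ...]
    has_week: bool
    has_interaction: bool
    week_range: tuple[float, float]

    def wald_group(self) -> tuple[float, float]:
        """Omnibus Wald F test that all group offsets are zero."""
        names = [n for n in self.params.index if n.startswith("group[")
                 and not n.endswith(":week")]
        c = self.params[names].to_numpy()
        v = self.cov_params.loc[names, names].to_numpy()
        q = len(names)
        f = float(c @ np.linalg.solve(v, c)) / q
        return f, float(stats.f.sf(f, q, self.df_resid))


def _whiten(times: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Sequential AR(1) whitening weights for one ordered time grid.

    Returns (lag coefficients r_j, scale 1/sqrt(1-r_j^2), logdet of the
    correlation matrix); index 0 corresponds to the undifferenced first
    observation.
    """
    gaps = np.diff(times)
    if np.any(gaps <= 0):
        raise DomainError("time points within a cage must be strictly increasing")
    if rho < 0 and not np.allclose(gaps, np.round(gaps)):
        raise DomainError("negative rho undefined for non-integer lags")
    r = np.sign(rho) ** np.round(gaps).astype(int) * np.abs(rho) ** gaps if rho < 0 else rho**gaps
    scale = 1.0 / np.sqrt(1.0 - r**2)
    logdet = float(np.sum(np.log(1.0 - r**2)))
    return r, scale, logdet


def _build_design(
    df: pd.DataFrame,
    control: str,
    groups: Sequence[str],
    include_week: bool,
    include_interaction: bool,
    gender_factor: bool,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for g in groups:
        if g == control:
            continue
        cols.append((df["group"] == g).to_numpy(float))
        names.append(f"group[{g}]")
    if gender_factor:
        genders = sorted(df["gender"].unique())
        for g in genders[1:]:
            cols.append((df["gender"] == g).to_numpy(float))
            names.append(f"gender[{g}]")
    if include_week:
        cols.append(df["time"].to_numpy(float))
        names.append("week")
    if include_interaction:
        if not include_week:
            raise DomainError("interaction requires the week term")
        for g in groups:
            if g == control:
                continue
            cols.append((df["group"] == g).to_numpy(float) * df["time"].to_numpy(float))
            names.append(f"group[{g}]:week")
    x = np.column_stack(cols)
    return x, names


def fit_gls_ar1(
    series_table: pd.DataFrame,
    design: TrialDesign | None = None,
    control: str = "control",
    include_week: bool = True,
    include_interaction: bool = False,
    gender_factor: bool = False,
    rho_bounds: tuple[float, float] | None = None,
) -> LongitudinalFit:
    """Fit the AR(1)-GLS model to a cage-level longitudinal table
    (columns cage_id, group, gender, time, value) by REML.

    Raises :class:`RankError` naming the aliased column on singular
    designs; non-convergence of the scalar search is reported through
    ``converged`` with the last iterate, never silently.
    """
    df = series_table.sort_values(["cage_id", "time"]).reset_index(drop=True)
    control = design.control if design is not None else control
    groups = tuple(design.groups) if design is not None else tuple(
        pd.unique(df["group"])
    )
    x, names = _build_design(df, control, groups, include_week, include_interaction,
                             gender_factor)
    y = df["value"].to_numpy(float)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        for j in range(p):
            others = np.delete(np.arange(p), j)
            if np.linalg.matrix_rank(x[:, others]) == np.linalg.matrix_rank(x):
                raise RankError(f"design column {names[j]!r} is aliased")
        raise RankError("design matrix is rank deficient")

    cage_slices = []
    for _, idx in df.groupby("cage_id", sort=False).indices.items():
        idx = np.asarray(idx)
        cage_slices.append((idx, df["time"].to_numpy(float)[idx]))
    min_t = min(len(t) for _, t in cage_slices)
    if min_t < 1:
        raise DomainError("each cage needs at least one time point")

    integer_gaps = all(
        np.allclose(np.diff(t), np.round(np.diff(t))) for _, t in cage_slices if len(t) > 1
    )
    if rho_bounds is None:
        rho_bounds = (-RHO_BOUND if integer_gaps else 0.0, RHO_BOUND)

    def _whitened(rho: float) -> tuple[np.ndarray, np.ndarray, float]:
        xs = np.empty_like(x)
        ys = np.empty_like(y)
        logdet = 0.0
        for idx, t in cage_slices:
            xs[idx[0]] = x[idx[0]]
            ys[idx[0]] = y[idx[0]]
            if len(idx) > 1:
                r, scale, ld = _whiten(t, rho)
                logdet += ld
                xs[idx[1:]] = (x[idx[1:]] - r[:, None] * x[idx[:-1]]) * scale[:, None]
                ys[idx[1:]] = (y[idx[1:]] - r * y[idx[:-1]]) * scale
        return xs, ys, logdet

    def neg_reml(rho: float) -> float:
        xs, ys, logdet_v = _whitened(rho)
        beta, *_ = np.linalg.lstsq(xs, ys, rcond=None)
        resid = ys - xs @ beta
        rss = float(resid @ resid)
        sigma2 = rss / (n - p)
        sign, logdet_xtx = np.linalg.slogdet(xs.T @ xs)
        if sign <= 0 or sigma2 <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * math.log(2 * math.pi * sigma2) + (n - p)
            + logdet_v + logdet_xtx
        )
        return -ll

    if max(len(t) for _, t in cage_slices) < 2:
        # no within-cage lags: the correlation parameter is unidentified
        res_rho, converged = 0.0, True
    else:
        opt = optimize.minimize_scalar(
            neg_reml, bounds=rho_bounds, method="bounded",
            options={"xatol": 1e-6},
        )
        res_rho, converged = float(opt.x), bool(opt.success)
        if not converged:
            logger.warning("REML rho search did not converge; last iterate %.4f", res_rho)

    xs, ys, _ = _whitened(res_rho)
    xtx = xs.T @ xs
    beta = np.linalg.solve(xtx, xs.T @ ys)
    resid = ys - xs @ beta
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    params = pd.Series(beta, index=names)
    cov_params = pd.DataFrame(cov, index=names, columns=names)

    rows = []
    for g in groups:
        if g == control:
            continue
        name = f"group[{g}]"
        est = float(params[name])
        se = math.sqrt(float(cov_params.loc[name, name]))
        tstat = est / se if se > 0 else math.copysign(math.inf, est)
        pval = 2 * float(stats.t.sf(abs(tstat), n - p))
        ci = stats.t.ppf(0.975, n - p) * se
        rows.append({"group": g, "estimate": est, "se": se, "t": tstat,
                     "p_value": pval, "ci_lo": est - ci, "ci_hi": est + ci})
    contrasts = pd.DataFrame(rows)

    return LongitudinalFit(
        params=params, cov_params=cov_params, rho=res_rho, sigma2=sigma2,
        reml_loglik=-neg_reml(res_rho), df_resid=n - p, contrasts=contrasts,
        converged=converged, control=control,
        groups=tuple(g for g in groups if (series_table["group"] == g).any()),
        has_week=include_week, has_interaction=include_interaction,
        week_range=(float(df["time"].min()), float(df["time"].max())),
    )


def lsmeans(fit: LongitudinalFit, at_week: float) -> pd.DataFrame:
    """Model-predicted group means at ``at_week`` with delta-method SEs and
    contrasts against the control group (these feed the SES computation for
    least-square-mean body weights)."""
    if not fit.converged:
        raise DomainError("fit did not converge; refusing to predict")
    lo, hi = fit.week_range
    if fit.has_week and not (lo <= at_week <= hi):
        logger.warning("lsmeans at week %.1f extrapolates beyond observed [%g, %g]",
                       at_week, lo, hi)
    names = list(fit.params.index)

    def row_for(group: str) -> np.ndarray:
        x = np.zeros(len(names))
        for j, nm in enumerate(names):
            if nm == "intercept":
                x[j] = 1.0
            elif nm == "week":
                x[j] = at_week
            elif nm == f"group[{group}]":
                x[j] = 1.0
            elif nm == f"group[{group}]:week":
                x[j] = at_week
            elif nm.startswith("gender["):
                x[j] = 0.5  # average over genders in pooled fits
        return x

    cov = fit.cov_params.to_numpy()
    beta = fit.params.to_numpy()
    x0 = row_for(fit.control)
    rows = []
    for g in fit.groups:
        xg = row_for(g)
        est = float(xg @ beta)
        se = math.sqrt(float(xg @ cov @ xg))
        rec = {"group": g, "lsmean": est, "se": se}
        if g != fit.control:
            d = xg - x0
            c_est = float(d @ beta)
            c_se = math.sqrt(float(d @ cov @ d))
            t = c_est / c_se if c_se > 0 else math.copysign(math.inf, c_est)
            rec.update(
                contrast=c_est, contrast_se=c_se,
                p_value=2 * float(stats.t.sf(abs(t), fit.df_resid)),
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def analyze_longitudinal(
    series_table: pd.DataFrame,
    design: TrialDesign,
    **kwargs,
) -> dict[str, LongitudinalFit]:
    """The batch driver: one pooled fit with gender as a fixed factor plus
    one fit per gender, as the trial analysed growth data combined and
    separately for male and female animals."""
    fits = {
        "pooled": fit_gls_ar1(series_table, design, gender_factor=True, **kwargs)
    }
    for gender in design.genders:
        sub = series_table[series_table["gender"] == gender]
        if len(sub):
            fits[gender] = fit_gls_ar1(sub, design, **kwargs)
    return fits
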