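"""Shared independent oracles for the test suite (kept free of any
dependence on the implementation paths they check)."""

import itertools

import numpy as np
import pandas as pd
from scipy import stats


def exact_ranksum_p(a, b) -> float:
    """Exhaustive enumeration oracle for the two-sided rank-sum p-value:
    fraction of label arrangements with a rank sum at least as far from its
    null mean as observed."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = len(a)
    observed = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-9:
            count += 1
    return count / total


def simulate_panel(
    rho: float,
    slope: float = 5.0,
    offset: float = -20.0,
    sigma: float = 10.0,
    n_cages: int = 10,
    weeks=tuple(range(1, 14)),
    seed: int = 0,
    gender: str = "male",
) -> pd.DataFrame:
    """Two-group AR(1) longitudinal panel with known fixed effects."""
    rng = np.random.default_rng(seed)
    t = np.asarray(weeks, float)
    rows = []
    for group, shift in (("control", 0.0), ("treated", offset)):
        for c in range(n_cages):
            e = np.empty(t.size)
            e[0] = rng.normal(0, sigma)
            for j in range(1, t.size):
                r = rho ** (t[j] - t[j - 1])
                e[j] = r * e[j - 1] + rng.normal(0, sigma * np.sqrt(1 - r**2))
            for j in range(t.size):
                rows.append(
                    (f"{group}-{c:02d}", gender, group, t[j],
                     100.0 + shift + slope * t[j] + e[j])
                )
    return pd.DataFrame(rows, columns=["cage_id", "gender", "group", "time", "value"])


def mc_t_test_power(d: float, n: int, alpha: float, n_rep: int, seed: int) -> float:
    """Monte-Carlo power of the two-sided pooled two-sample t-test,
    simulated from raw normal samples in chunks."""
    rng = np.random.default_rng(seed)
    crit = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
    hits = 0
    done = 0
    while done < n_rep:
        chunk = min(200_000, n_rep - done)
        x = rng.standard_normal((chunk, n))
        y = rng.standard_normal((chunk, n)) + d
        sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2.0
        t = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(sp2 * 2.0 / n)
        hits += int(np.sum(np.abs(t) > crit))
        done += chunk
    return hits / n_rep


def mc_dunnett_max_t(
    ns: list[int], n0: int, n_rep: int, seed: int
) -> np.ndarray:
    """Monte-Carlo oracle draws of max_i |T_i| for Dunnett's many-to-one
    statistics, simulated from raw normal group samples (null world)."""
    rng = np.random.default_rng(seed)
    sizes = [n0] + list(ns)
    df = sum(sizes) - len(sizes)
    out = np.empty(n_rep)
    done = 0
    while done < n_rep:
        chunk = min(200_000, n_rep - done)
        means, sss = [], []
        for sz in sizes:
            x = rng.standard_normal((chunk, sz))
            means.append(x.mean(axis=1))
            sss.append(((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
        mse = np.sum(sss, axis=0) / df
        m0 = means[0]
        ts = [
            np.abs(means[i + 1] - m0) / np.sqrt(mse * (1.0 / ns[i] + 1.0 / n0))
            for i in range(len(ns))
        ]
        out[done : done + chunk] = np.max(ts, axis=0)
        done += chunk
    return out
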