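"""Cross-method concordance, the all-endpoints-at-a-glance SES panel
graphic, and the end-to-end pipeline driver.

Concordance is defined over the binary significant/non-significant status
of each treatment-vs-control comparison: agreement between two methods is
the percentage of comparisons on which their flags coincide.  For the SES
method, "significant" means the 95 % CI excludes zero (cases b or c),
ignoring the relevance classification.  Degenerate (zero-variance)
comparisons are excluded from the universe and listed in the run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .classical_analysis import (
    SINGLE_METHODS,
    classical_batch,
    classical_flags,
    classical_to_frame,
    run_single_method,
)
from .errors import ConsistencyError
from .longitudinal import analyze_longitudinal
from .ses_analysis import (
    DEFAULT_LIMITS,
    RelevanceLimits,
    SESResult,
    results_to_frame,
    ses_batch,
)
from .synthetic_data import GrowthSpec, NULL_EFFECTS, default_panel, simulate_growth, simulate_trial
from .trial_model import DEFAULT_DESIGN, TrialDesign, cage_aggregate, group_summary, write_table

logger = logging.getLogger(__name__)

CASE_COLORS = {"a": "#2b7a2b", "b": "#d98a00", "c": "#c22525", "d": "#5b6ee1"}
CASE_LABELS = {
    "a": "a: not significant, within limits",
    "b": "b: significant, relevance unclear",
    "c": "c: significant, outside limits",
    "d": "d: not significant, inconclusive",
}


@dataclass(frozen=True)
class ConcordanceSummary:
    universe: int
    counts: Mapping[str, int]
    agreement: pd.DataFrame  # percent, symmetric, diagonal 100
    discordant: pd.DataFrame  # one row per comparison where any pair differs


def concordance(flag_matrices: Mapping[str, pd.Series]) -> ConcordanceSummary:
    """Pairwise agreement of binary significance flags over a shared
    comparison universe.  Raises :class:`ConsistencyError` listing the
    offending keys on index mismatch."""
    methods = list(flag_matrices)
    if not methods:
        raise ConsistencyError("no flag matrices given")
    base = flag_matrices[methods[0]].sort_index()
    for m in methods[1:]:
        other = flag_matrices[m].sort_index()
        if not base.index.equals(other.index):
            missing = base.index.symmetric_difference(other.index)
            raise ConsistencyError(
                f"flag index mismatch between {methods[0]!r} and {m!r}: "
                f"{list(missing[:5])}"
            )
    frame = pd.DataFrame({m: flag_matrices[m].sort_index() for m in methods}).astype(bool)
    e = len(frame)
    counts = {m: int(frame[m].sum()) for m in methods}
    agree = pd.DataFrame(100.0, index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            pct = 100.0 * float((frame[a] == frame[b]).mean()) if e else 100.0
            agree.loc[a, b] = agree.loc[b, a] = pct
    disagreeing = frame[frame.nunique(axis=1) > 1] if e else frame
    return ConcordanceSummary(e, counts, agree, disagreeing.reset_index())


def ses_panel_plot(
    ses_results: Sequence[SESResult],
    limits: RelevanceLimits = DEFAULT_LIMITS,
    output_path: str | Path = "ses_panel.svg",
) -> Path:
    """All endpoints at a glance: one panel per (gender, comparison group)
    with the SES point estimate and 95 % CI per endpoint-time, a zero line
    and the +/-L relevance lines.  Rendering is deterministic for fixed
    inputs (fixed SVG hash salt, no timestamps)."""
    if not ses_results:
        raise ConsistencyError("no SES results to plot")
    frame = results_to_frame(list(ses_results))
    frame = frame[~frame["degenerate"]]
    genders = sorted(frame["gender"].unique())
    groups = list(dict.fromkeys(frame["group"]))
    n_rows, n_cols = len(genders), len(groups)

    with plt.rc_context({"svg.hashsalt": "cagestat"}):
        fig, axes = plt.subplots(
            n_rows, n_cols, sharex=True, squeeze=False,
            figsize=(4.0 * n_cols, 0.14 * frame.groupby(["gender", "group"]).size().max() + 2.0),
        )
        for i, gender in enumerate(genders):
            for j, grp in enumerate(groups):
                ax = axes[i][j]
                sub = frame[(frame["gender"] == gender) & (frame["group"] == grp)]
                sub = sub.sort_values(["endpoint", "time"]).reset_index(drop=True)
                y = np.arange(len(sub))
                for case in "abcd":
                    pick = sub["case"] == case
                    if pick.any():
                        d = sub.loc[pick, "d"].to_numpy()
                        ax.errorbar(
                            d, y[pick],
                            xerr=[
                                d - sub.loc[pick, "ci_lo"].to_numpy(),
                                sub.loc[pick, "ci_hi"].to_numpy() - d,
                            ],
                            fmt="o", ms=3, lw=1, color=CASE_COLORS[case],
                            label=CASE_LABELS[case],
                        )
                ax.axvline(0.0, color="black", lw=1)
                for v in (-limits.limit, limits.limit):
                    ax.axvline(v, color="grey", lw=1, ls="--")
                ax.set_title(f"{gender}: {grp} vs control", fontsize=9)
                if j == 0:
                    ax.set_yticks(y)
                    ax.set_yticklabels(
                        [f"{e} (t={t:g})" for e, t in zip(sub["endpoint"], sub["time"])],
                        fontsize=5,
                    )
                else:
                    ax.set_yticks([])
                ax.set_xlabel("standardized effect size (SD units)", fontsize=8)
        handles, labels = [], []
        for ax in fig.axes:
            h, l = ax.get_legend_handles_labels()
            for hh, ll in zip(h, l):
                if ll not in labels:
                    handles.append(hh)
                    labels.append(ll)
        # legend enumerates every case present in the results
        fig.legend(handles, labels, loc="lower center", ncol=min(4, max(1, len(labels))),
                   fontsize=8, frameon=False)
        fig.tight_layout(rect=(0, 0.05, 1, 1))
        output_path = Path(output_path)
        fig.savefig(output_path, metadata=_plot_metadata(output_path.suffix))
        plt.close(fig)
    return output_path


def _plot_metadata(suffix: str) -> dict:
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".pdf":
        return {"CreationDate": None}
    return {}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(
    design: TrialDesign = DEFAULT_DESIGN,
    seed: int = 0,
    out_dir: str | Path = "cagestat_report",
    limits: RelevanceLimits = DEFAULT_LIMITS,
    effect_spec=NULL_EFFECTS,
    alpha: float = 0.05,
    endpoint_specs=None,
    growth_spec: GrowthSpec | None = None,
) -> dict:
    """End-to-end pipeline on a (by default synthetic null) trial:
    simulate -> aggregate -> SES batch -> decision-tree batch -> three
    single-method batches -> longitudinal fits -> concordance -> plots and
    tables.  Returns the manifest (also written as JSON) recording the
    version, seed, parameter hash, per-stage status and output hashes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "design_hash": hashlib.sha256(
            json.dumps(design.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "alpha": alpha,
        "relevance_limit": limits.limit,
        "stages": [],
        "outputs": {},
    }

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        specs = endpoint_specs if endpoint_specs is not None else default_panel(design)
        panel = simulate_trial(design, specs, effect_spec, seed=seed)
        growth = simulate_growth(design, growth_spec, seed=seed)

        stage("aggregate")
        cage = cage_aggregate(panel, design)
        cage_growth = cage_aggregate(growth, design)
        summaries = group_summary(cage)
        write_table(cage, out / "cage_table.csv")
        write_table(summaries, out / "group_summary.csv")

        stage("ses")
        ses = ses_batch(cage, design, limits=limits)
        ses_frame = results_to_frame(ses)
        write_table(ses_frame, out / "ses_results.csv")
        ok = ses_frame[~ses_frame["degenerate"]]
        ses_flags = ok.set_index(["gender", "endpoint", "time", "group"])[
            "significant"
        ].sort_index()
        manifest["n_comparisons"] = int(len(ok))
        manifest["excluded_degenerate"] = [
            list(map(str, t))
            for t in ses_frame.loc[ses_frame["degenerate"],
                                   ["gender", "endpoint", "time", "group"]].itertuples(index=False)
        ]

        stage("classical")
        tree = classical_batch(cage, design, alpha=alpha)
        write_table(classical_to_frame(tree, design), out / "classical_results.csv")
        tree_flags = classical_flags(tree, design).reindex(ses_flags.index)

        stage("single_methods")
        singles = {
            m: run_single_method(cage, m, design, alpha=alpha).reindex(ses_flags.index)
            for m in SINGLE_METHODS
        }

        stage("longitudinal")
        weight = cage_growth[cage_growth["endpoint"] == "body_weight"]
        fits = analyze_longitudinal(weight, design)
        long_summary = {
            name: {
                "rho": fit.rho,
                "sigma2": fit.sigma2,
                "converged": fit.converged,
                "contrasts": fit.contrasts.to_dict(orient="records"),
            }
            for name, fit in fits.items()
        }
        (out / "longitudinal.json").write_text(json.dumps(long_summary, indent=2, default=float))

        stage("concordance")
        matrices = {"ses": ses_flags, "decision_tree": tree_flags, **singles}
        conc = concordance(matrices)
        write_table(conc.agreement.reset_index(names="method"), out / "agreement.csv")
        write_table(conc.discordant, out / "discordant.csv")
        manifest["significant_counts"] = conc.counts
        manifest["agreement_ses_vs_tree"] = float(conc.agreement.loc["ses", "decision_tree"])

        stage("plots")
        fig_path = ses_panel_plot(ses, limits, out / "ses_panel.svg")
        manifest["outputs"] = {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json", ".svg") and p.name != "manifest.json"
        }
        manifest["outputs"][fig_path.name] = _sha256(fig_path)
    except Exception as exc:  # partial outputs are retained on purpose
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise ConsistencyError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
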