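"""Synthetic feeding-trial generator.

Emulates the hierarchical structure the analysis assumes: per-endpoint
group effects expressed in cage-mean SD units, cage random effects, animal
residuals, deterministic growth curves with multiplicative noise, and
endpoint panels sampled at interim and terminal months.

The data-generating model for a quantitative endpoint is

    y_animal = mu + delta * sigma + u_cage + eps,
    u_cage ~ N(0, (1 - w) sigma^2),
    eps    ~ N(0, w sigma^2 * m),        m = animals per cage,

so the *cage mean* has variance (1-w) sigma^2 + w sigma^2 m / m = sigma^2
exactly and ``delta`` is the directly recoverable standardized effect on
the cage-mean scale — the scale on which the trial's power analysis and
relevance limits are defined.  ``w`` is the share of cage-mean variance
contributed by animal residuals.  Lognormal endpoints apply the same
construction on the log scale.

One global seed drives a splittable per-endpoint stream (the stream key is
a CRC-32 of the endpoint name), so adding endpoints never perturbs the
values of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .trial_model import DEFAULT_DESIGN, MEASUREMENT_COLUMNS, TrialDesign


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndpointSpec:
    """Distributional spec for one endpoint.

    ``mean`` may be a scalar, a ``{gender: scalar}`` map, or a
    ``{gender: {time: scalar}}`` map; ``sd`` is the cage-mean standard
    deviation sigma_e; ``within_frac`` is w, the animal-residual share of
    cage-mean variance.  ``times=None`` means the endpoint is observed at
    every design observation month.  Ordinal endpoints are produced by
    thresholding the latent normal construction at ``bin_edges``.
    """

    name: str
    mean: float | Mapping = 0.0
    sd: float = 1.0
    within_frac: float = 0.5
    dist: str = "normal"  # "normal" | "lognormal"
    kind: str = "quantitative"  # "quantitative" | "qualitative-ordinal"
    times: tuple[int, ...] | None = None
    bin_edges: tuple[float, ...] = ()
    unit: str = ""

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"{self.name}: sd must be positive")
        if not 0 <= self.within_frac < 1:
            raise ConfigurationError(f"{self.name}: within_frac must be in [0, 1)")
        if self.dist not in ("normal", "lognormal"):
            raise ConfigurationError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.kind == "qualitative-ordinal" and not self.bin_edges:
            raise ConfigurationError(f"{self.name}: ordinal endpoint needs bin_edges")

    def mean_at(self, gender: str, time: float) -> float:
        m = self.mean
        if isinstance(m, Mapping):
            if gender not in m:
                raise ConfigurationError(f"{self.name}: no mean for gender {gender!r}")
            m = m[gender]
            if isinstance(m, Mapping):
                if time not in m:
                    raise ConfigurationError(
                        f"{self.name}: no mean for gender {gender!r} at time {time}"
                    )
                m = m[time]
        return float(m)


@dataclass(frozen=True)
class EffectSpec:
    """Standardized group effects delta in cage-mean SD units.

    ``effects`` maps keys of decreasing specificity to delta:
    ``(group, gender, endpoint, time)``, ``(group, gender, endpoint)``,
    ``(group, endpoint)`` or ``group``.  The control group always has
    delta = 0.
    """

    effects: Mapping = field(default_factory=dict)
    control: str = "control"

    def __post_init__(self) -> None:
        for key in self.effects:
            g = key[0] if isinstance(key, tuple) else key
            if g == self.control and self.effects[key] != 0:
                raise ConfigurationError("control group must have delta = 0")

    def delta(self, group: str, gender: str, endpoint: str, time: float) -> float:
        if group == self.control:
            return 0.0
        for key in (
            (group, gender, endpoint, time),
            (group, gender, endpoint),
            (group, endpoint),
            group,
        ):
            if key in self.effects:
                return float(self.effects[key])
        return 0.0


NULL_EFFECTS = EffectSpec()


@dataclass(frozen=True)
class GenderGrowth:
    """Monomolecular growth parameters for one gender.

    W(t) = A - (A - W0) exp(-k t), t in weeks; the feed-intake curve per
    cage ramps linearly from ``feed_baseline`` to ``feed_plateau`` g/week
    at ``feed_plateau_week`` and stays flat.
    """

    w0: float
    asymptote: float
    rate: float
    cv: float = 0.03
    feed_baseline: float = 280.0
    feed_plateau: float = 380.0
    feed_plateau_week: int = 5
    feed_cv: float = 0.05

    def __post_init__(self) -> None:
        if not (self.asymptote > self.w0 > 0):
            raise ConfigurationError("need asymptote > W0 > 0")
        if self.rate <= 0 or self.cv < 0:
            raise ConfigurationError("need rate > 0 and cv >= 0")

    def weight_at(self, week: float) -> float:
        return self.asymptote - (self.asymptote - self.w0) * np.exp(-self.rate * week)

    def intake_at(self, week: float) -> float:
        ramp = min(week / self.feed_plateau_week, 1.0)
        return self.feed_baseline + (self.feed_plateau - self.feed_baseline) * ramp


@dataclass(frozen=True)
class GrowthSpec:
    """Growth and feed-intake parameters per gender.

    Defaults are calibrated so the terminal mean body weight of the
    noise-free curve lands near the ~594 g (male) and ~358 g (female)
    anchors of a 1-year Wistar Han trial.
    """

    per_gender: Mapping[str, GenderGrowth] = field(
        default_factory=lambda: {
            "male": GenderGrowth(w0=150.0, asymptote=600.0, rate=0.08,
                                 feed_baseline=280.0, feed_plateau=380.0),
            "female": GenderGrowth(w0=110.0, asymptote=360.0, rate=0.09,
                                   feed_baseline=200.0, feed_plateau=260.0),
        }
    )


# ---------------------------------------------------------------------------
# Layout helpers
# ---------------------------------------------------------------------------


def _endpoint_rng(seed: int, endpoint: str) -> np.random.Generator:
    """Deterministic per-endpoint stream split from the global seed."""
    key = zlib.crc32(endpoint.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def cage_layout(design: TrialDesign) -> pd.DataFrame:
    """One row per animal with its cage, group and gender assignment."""
    rows = []
    animal = 1
    for gender in design.genders:
        for group in design.groups:
            for c in range(1, design.cages_per_group_per_gender + 1):
                cage_id = f"{gender[0].upper()}-{group}-{c:02d}"
                for _ in range(design.animals_per_cage):
                    rows.append((f"A{animal:04d}", cage_id, gender, group))
                    animal += 1
    return pd.DataFrame(rows, columns=["animal_id", "cage_id", "gender", "group"])


def _sampled_layout(design: TrialDesign, time: float) -> pd.DataFrame:
    """Animals observed at a time point: the first ``subsample_n`` animals
    (whole cages first) per group and gender at interim months, everyone at
    the final month."""
    layout = cage_layout(design)
    if time == design.observation_months[-1]:
        return layout
    return (
        layout.groupby(["gender", "group"], sort=False, group_keys=False)
        .head(design.subsample_n)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_trial(
    design: TrialDesign = DEFAULT_DESIGN,
    endpoint_specs: Sequence[EndpointSpec] = (),
    effect_spec: EffectSpec = NULL_EFFECTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-animal endpoint panels for a complete trial.

    Returns a tidy measurement table in the schema :mod:`cagestat.trial_model`
    reads.  Identical seeds give identical tables.
    """
    if not endpoint_specs:
        raise ConfigurationError("no endpoint specs given")
    m = design.animals_per_cage
    frames = []
    for spec in endpoint_specs:
        rng = _endpoint_rng(seed, spec.name)
        times = spec.times if spec.times is not None else design.observation_months
        for time in times:
            layout = _sampled_layout(design, time)
            cages = layout["cage_id"].unique()
            u = dict(zip(cages, rng.normal(0.0, spec.sd * np.sqrt(1 - spec.within_frac), cages.size)))
            eps_sd = spec.sd * np.sqrt(spec.within_frac * m)
            eps = rng.normal(0.0, eps_sd, len(layout))
            mu = np.array([spec.mean_at(g, time) for g in layout["gender"]])
            delta = np.array(
                [
                    effect_spec.delta(row.group, row.gender, spec.name, time)
                    for row in layout.itertuples()
                ]
            )
            latent = mu + delta * spec.sd + layout["cage_id"].map(u).to_numpy() + eps
            if spec.dist == "lognormal":
                value = np.exp(latent)
            else:
                value = latent
            if spec.kind == "qualitative-ordinal":
                value = np.digitize(latent, spec.bin_edges).astype(float)
            frame = layout.copy()
            frame["endpoint"] = spec.name
            frame["time"] = time
            frame["value"] = value
            frame["kind"] = spec.kind
            frame["unit"] = spec.unit
            frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[list(MEASUREMENT_COLUMNS) + ["kind", "unit"]]


def simulate_growth(
    design: TrialDesign = DEFAULT_DESIGN,
    growth_spec: GrowthSpec | None = None,
    seed: int = 0,
    asymptote_shift: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Simulate longitudinal body weight (per animal per recording week) and
    feed consumption (per cage per recording period, as the cage total).

    ``asymptote_shift`` maps ``(group, gender)`` to a shift in grams applied
    to the growth asymptote, for simulating group effects on weight.
    Multiplicative noise is lognormal with coefficient of variation ``cv``
    and unit mean.
    """
    growth_spec = growth_spec or GrowthSpec()
    shifts = asymptote_shift or {}
    layout = cage_layout(design)
    weeks = design.recording_weeks
    frames = []

    rng_w = _endpoint_rng(seed, "body_weight")
    rows = []
    for row in layout.itertuples():
        g = growth_spec.per_gender[row.gender]
        shift = shifts.get((row.group, row.gender), 0.0)
        a = g.asymptote + shift
        sig = np.sqrt(np.log1p(g.cv**2))
        for week in weeks:
            curve = a - (a - g.w0) * np.exp(-g.rate * week)
            noise = np.exp(rng_w.normal(-sig**2 / 2, sig)) if g.cv > 0 else 1.0
            rows.append(
                (row.animal_id, row.cage_id, row.gender, row.group,
                 "body_weight", week, curve * noise, "quantitative", "g")
            )
    frames.append(pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS) + ["kind", "unit"]))

    rng_f = _endpoint_rng(seed, "feed_consumption")
    rows = []
    cages = layout.drop_duplicates("cage_id")
    for row in cages.itertuples():
        g = growth_spec.per_gender[row.gender]
        sig = np.sqrt(np.log1p(g.feed_cv**2))
        prev = 0
        for week in weeks:
            period = week - prev  # 1 week early on, 2 weeks later
            prev = week
            total = g.intake_at(week) * period
            noise = np.exp(rng_f.normal(-sig**2 / 2, sig)) if g.feed_cv > 0 else 1.0
            # feed is recorded once per cage-period as the cage total
            rows.append(
                (row.cage_id, row.cage_id, row.gender, row.group,
                 "feed_consumption", week, total * noise, "quantitative", "g")
            )
    frames.append(pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS) + ["kind", "unit"]))
    return pd.concat(frames, ignore_index=True)


def replicate_cage_means(
    n_rep: int,
    n_cages: int,
    animals_per_cage: int = 2,
    mu: float = 0.0,
    sigma: float = 1.0,
    within_frac: float = 0.5,
    delta: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Vectorized replicate draws of one group's cage means under the
    hierarchical model of :func:`simulate_trial` (for calibration studies).

    Returns an array of shape ``(n_rep, n_cages)``; each cage mean has
    variance sigma^2 exactly.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma * np.sqrt(1 - within_frac), size=(n_rep, n_cages))
    eps = rng.normal(
        0.0,
        sigma * np.sqrt(within_frac * animals_per_cage),
        size=(n_rep, n_cages, animals_per_cage),
    )
    return mu + delta * sigma + u + eps.mean(axis=2)


# ---------------------------------------------------------------------------
# Default endpoint panel
# ---------------------------------------------------------------------------


def default_panel(design: TrialDesign = DEFAULT_DESIGN) -> list[EndpointSpec]:
    """Default endpoint panel emulating a chronic-toxicity battery.

    29 haematology / differential-count / clinical-biochemistry endpoints
    observed at every observation month plus 13 relative organ weights at
    necropsy only: 100 endpoint-time cells per gender, hence about 600
    treatment-vs-control comparisons in the default four-group design.
    Control means and SDs are loose physiological magnitudes for an adult
    Wistar rat; they parameterize the generator, they do not reproduce any
    measured data set.
    """
    terminal = (design.observation_months[-1],)
    haematology = [
        EndpointSpec("WBC", {"male": 8.0, "female": 6.3}, 0.9, unit="10^3/ul"),
        EndpointSpec("RBC", {"male": 8.3, "female": 7.6}, 0.25, unit="10^6/ul"),
        EndpointSpec("HGB", {"male": 16.2, "female": 15.5}, 0.45, unit="g/dl"),
        EndpointSpec("HCT", {"male": 45.7, "female": 43.8}, 1.4, unit="%"),
        EndpointSpec("MCV", {"male": 55.5, "female": 57.6}, 1.0, unit="fl"),
        EndpointSpec("MCH", {"male": 19.6, "female": 20.4}, 0.55, unit="pg"),
        EndpointSpec("MCHC", {"male": 35.4, "female": 35.3}, 0.5, unit="g/dl"),
        EndpointSpec("PLT", {"male": 730.0, "female": 720.0}, 90.0, unit="10^3/ul"),
        EndpointSpec("LYM", {"male": 5.8, "female": 4.3}, 0.95, unit="10^3/ul"),
        EndpointSpec("lymphocytes_pct", {"male": 66.0, "female": 68.0}, 4.2, unit="%"),
        EndpointSpec("neutrophils_pct", {"male": 28.0, "female": 26.5}, 4.0, unit="%"),
        EndpointSpec("monocytes_pct", {"male": 3.2, "female": 2.7}, 0.7, unit="%"),
        # lognormal: mean/sd parameterize the log scale (median exp(0.73)≈2.1 %)
        EndpointSpec("eosinophils_pct", {"male": 0.73, "female": 0.78}, 0.35,
                     dist="lognormal", unit="%"),
        EndpointSpec("basophils_pct", {"male": 0.4, "female": 0.4}, 0.12, unit="%"),
    ]
    biochemistry = [
        EndpointSpec("ALP", {"male": 1.25, "female": 0.6}, 0.16, unit="ukat/l"),
        EndpointSpec("ALT", {"male": 0.55, "female": 0.58}, 0.16, unit="ukat/l"),
        EndpointSpec("AST", {"male": 2.4, "female": 2.9}, 0.6, unit="ukat/l"),
        EndpointSpec("ALB", {"male": 39.0, "female": 45.0}, 2.1, unit="g/l"),
        EndpointSpec("TP", {"male": 67.0, "female": 72.0}, 2.5, unit="g/l"),
        EndpointSpec("GLU", {"male": 6.6, "female": 6.6}, 0.8, unit="mmol/l"),
        EndpointSpec("CREA", {"male": 45.0, "female": 45.5}, 4.5, unit="umol/l"),
        EndpointSpec("UREA", {"male": 5.7, "female": 6.0}, 0.6, unit="mmol/l"),
        EndpointSpec("CHOL", {"male": 2.35, "female": 2.1}, 0.27, unit="mmol/l"),
        EndpointSpec("TRG", {"male": 1.15, "female": 0.8}, 0.28, unit="mmol/l"),
        EndpointSpec("Ca", {"male": 2.6, "female": 2.58}, 0.06, unit="mmol/l"),
        EndpointSpec("Cl", {"male": 104.0, "female": 101.5}, 1.6, unit="mmol/l"),
        EndpointSpec("K", {"male": 5.2, "female": 4.9}, 0.5, unit="mmol/l"),
        EndpointSpec("Na", {"male": 145.0, "female": 142.5}, 1.5, unit="mmol/l"),
        EndpointSpec("P", {"male": 2.0, "female": 1.7}, 0.26, unit="mmol/l"),
    ]
    organs = [
        EndpointSpec(f"relweight_{organ}", {"male": mu_m, "female": mu_f}, sd,
                     times=terminal, unit="%")
        for organ, mu_m, mu_f, sd in [
            ("kidney_right", 0.234, 0.280, 0.022),
            ("kidney_left", 0.219, 0.262, 0.020),
            ("spleen", 0.182, 0.227, 0.026),
            ("liver", 2.370, 2.559, 0.170),
            ("adrenal_right", 0.004, 0.009, 0.001),
            ("adrenal_left", 0.004, 0.009, 0.0015),
            ("lung", 0.247, 0.305, 0.023),
            ("heart", 0.207, 0.248, 0.013),
            ("thymus", 0.095, 0.119, 0.017),
            ("pancreas", 0.124, 0.185, 0.022),
            ("gonad_right", 0.370, 0.012, 0.030),
            ("gonad_left", 0.366, 0.012, 0.030),
            ("brain", 0.391, 0.600, 0.045),
        ]
    ]
    return haematology + biochemistry + organs


def make_panel_fixture(seed: int = 0, design: TrialDesign = DEFAULT_DESIGN) -> pd.DataFrame:
    """A full default null trial whose analysis yields about 600
    treatment-vs-control endpoint comparisons (integration fixture)."""
    return simulate_trial(design, default_panel(design), NULL_EFFECTS, seed=seed)
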