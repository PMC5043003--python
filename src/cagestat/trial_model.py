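"""Domain model of a chronic rodent feeding trial.

The raw observation layer is a tidy per-animal table (one row per animal,
endpoint and observation time).  Because two animals share a cage and the
cage is the experimental unit, every inferential procedure in this package
runs on the *cage-aggregated* table produced by :func:`cage_aggregate`:
cage means for all endpoints except feed consumption, which is recorded as
the total amount eaten by the animals of one cage per period and is summed,
never averaged or halved.

The module also carries the small deterministic calculations the trial
design requires: feed efficiency, relative organ weights, Tukey-fence
extreme-value screening (flagging only — values are never removed),
contaminant dose from feed concentration, and the significant-figure ratio
arithmetic used for diet QC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConsistencyError, DomainError, SchemaError

logger = logging.getLogger(__name__)

#: Mandatory columns of the tidy measurement table.
MEASUREMENT_COLUMNS = (
    "animal_id",
    "cage_id",
    "gender",
    "group",
    "endpoint",
    "time",
    "value",
)

#: Optional columns with defaults filled on read.
OPTIONAL_COLUMNS = {"kind": "quantitative", "unit": ""}

CAGE_COLUMNS = (
    "cage_id",
    "gender",
    "group",
    "endpoint",
    "time",
    "value",
    "n_animals",
)

#: Endpoints aggregated per cage as totals rather than means.
TOTAL_ENDPOINTS = ("feed_consumption",)


# ---------------------------------------------------------------------------
# Trial design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialDesign:
    """Structure of the feeding trial.

    Parameters
    ----------
    groups
        Ordered diet group labels; ``control`` must be among them.
    control
        Label of the control group (exactly one).
    genders
        Gender labels, e.g. ``("male", "female")``.
    cages_per_group_per_gender
        Number of cages (experimental units) per group and gender.
    animals_per_cage
        Animals housed together in one cage.
    observation_months
        Strictly increasing panel sampling times in months.
    weekly_weeks
        Weeks with weekly body-weight/feed recording before the schedule
        switches to once every two weeks.
    final_week
        Last recorded week of the trial.
    subsample_n
        Animals per group and gender sampled at interim observation months
        (all animals are sampled at the final month).
    """

    groups: tuple[str, ...] = ("control", "conventional 2", "11 % GMO", "33 % GMO")
    control: str = "control"
    genders: tuple[str, ...] = ("male", "female")
    cages_per_group_per_gender: int = 10
    animals_per_cage: int = 2
    observation_months: tuple[int, ...] = (3, 6, 12)
    weekly_weeks: int = 13
    final_week: int = 53
    subsample_n: int = 10

    def __post_init__(self) -> None:
        if self.control not in self.groups:
            raise SchemaError(f"control group {self.control!r} not in groups")
        if len(set(self.groups)) != len(self.groups):
            raise SchemaError("group labels must be unique")
        if self.cages_per_group_per_gender < 2:
            raise SchemaError("need at least 2 cages per group and gender")
        if self.animals_per_cage < 1:
            raise SchemaError("animals_per_cage must be >= 1")
        if list(self.observation_months) != sorted(set(self.observation_months)):
            raise SchemaError("observation_months must be strictly increasing")

    @property
    def treatment_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if g != self.control)

    @property
    def recording_weeks(self) -> tuple[int, ...]:
        """Weeks at which body weight and feed are recorded: weekly during
        the first ``weekly_weeks`` weeks, once every 2 weeks thereafter."""
        weekly = list(range(1, self.weekly_weeks + 1))
        biweekly = list(range(self.weekly_weeks + 2, self.final_week + 1, 2))
        return tuple(weekly + biweekly)

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "control": self.control,
            "genders": list(self.genders),
            "cages_per_group_per_gender": self.cages_per_group_per_gender,
            "animals_per_cage": self.animals_per_cage,
            "observation_months": list(self.observation_months),
            "weekly_weeks": self.weekly_weeks,
            "final_week": self.final_week,
            "subsample_n": self.subsample_n,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialDesign":
        kwargs = dict(d)
        for key in ("groups", "genders", "observation_months"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "TrialDesign":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if "design" in doc:
            doc = doc["design"]
        return cls.from_dict(doc)


#: The packaged default reproduces the study design: 4 diet groups x
#: 2 genders x 10 cages x 2 animals, panels at months 3/6/12, 13 weekly
#: weeks then biweekly recording to week 53, interim subsample of 10.
DEFAULT_DESIGN = TrialDesign()


@dataclass(frozen=True)
class ExtremeFlag:
    """Tukey-fence screening result for one value (flag only, never drop)."""

    index: object
    value: float
    fence_low: float
    fence_high: float
    flagged: bool


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------


def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy measurement table against the schema invariants.

    Blank quantitative values are dropped with a logged warning.  Duplicate
    (animal, endpoint, time) keys and cages mapped to more than one
    (group, gender) raise :class:`ConsistencyError`.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"measurement table is missing columns: {missing}")
    table = table.copy()
    for col, default in OPTIONAL_COLUMNS.items():
        if col not in table.columns:
            table[col] = default

    blank = table["value"].isna()
    if blank.any():
        logger.warning("dropping %d record(s) with blank values", int(blank.sum()))
        table = table.loc[~blank]

    dupes = table.duplicated(subset=["animal_id", "endpoint", "time"])
    if dupes.any():
        keys = table.loc[dupes, ["animal_id", "endpoint", "time"]].head(5)
        raise ConsistencyError(
            f"duplicate (animal, endpoint, time) keys, e.g.:\n{keys.to_string(index=False)}"
        )

    cage_map = table.groupby("cage_id")[["group", "gender"]].nunique()
    bad = cage_map[(cage_map["group"] > 1) | (cage_map["gender"] > 1)]
    if len(bad):
        raise ConsistencyError(
            f"cage(s) mapped to more than one (group, gender): {list(bad.index)}"
        )

    quant = table["kind"] == "quantitative"
    if not np.isfinite(table.loc[quant, "value"].to_numpy(float)).all():
        raise ConsistencyError("non-finite value in a quantitative record")
    return table.reset_index(drop=True)


def read_measurements(path: str | Path, known_endpoints: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV of per-animal measurements and validate it.

    Unknown endpoint names (relative to ``known_endpoints``, if given) are
    allowed but logged.
    """
    table = pd.read_csv(path)
    table = validate_measurements(table)
    if known_endpoints is not None:
        unknown = sorted(set(table["endpoint"]) - set(known_endpoints))
        if unknown:
            logger.warning("unknown endpoint name(s): %s", unknown)
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV, bit-stable under fixed rounding (6 significant
    digits for floating-point columns)."""
    table.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Cage aggregation and summaries
# ---------------------------------------------------------------------------


def cage_aggregate(
    measurements: pd.DataFrame,
    design: TrialDesign | None = None,
    total_endpoints: Sequence[str] = TOTAL_ENDPOINTS,
) -> pd.DataFrame:
    """Aggregate per-animal records to one record per (cage, endpoint, time).

    Cage means for every endpoint except those in ``total_endpoints``
    (feed consumption), whose per-cage records are summed to the cage
    total.  Empty cages at a time point simply yield no record
    (early-sacrifice handling); the varying ``n_animals`` column records
    how many animals contributed.
    """
    measurements = validate_measurements(measurements)
    keys = ["cage_id", "gender", "group", "endpoint", "time"]
    is_total = measurements["endpoint"].isin(total_endpoints)

    parts = []
    mean_part = measurements.loc[~is_total]
    if len(mean_part):
        agg = mean_part.groupby(keys, sort=False)["value"].agg(["mean", "size"])
        agg = agg.rename(columns={"mean": "value", "size": "n_animals"}).reset_index()
        parts.append(agg)
    total_part = measurements.loc[is_total]
    if len(total_part):
        agg = total_part.groupby(keys, sort=False)["value"].agg(["sum", "size"])
        agg = agg.rename(columns={"sum": "value", "size": "n_animals"}).reset_index()
        parts.append(agg)

    cage = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=CAGE_COLUMNS)
    if design is not None:
        short = cage["n_animals"] < design.animals_per_cage
        over = cage["n_animals"] > design.animals_per_cage
        if over.any():
            raise ConsistencyError("more animal records in a cage than animals_per_cage")
        if short.any():
            logger.warning(
                "%d cage record(s) with fewer than %d contributing animals",
                int(short.sum()), design.animals_per_cage,
            )
    cage = cage.sort_values(["gender", "endpoint", "time", "group", "cage_id"], kind="mergesort")
    return cage.reset_index(drop=True)[list(CAGE_COLUMNS)]


def group_summary(cage_table: pd.DataFrame, conf_level: float = 0.95) -> pd.DataFrame:
    """Descriptive statistics per (group, gender, endpoint, time) over
    experimental units: n, mean, SD, min, max, median and a t-based
    confidence interval for the mean."""

    def _one(g: pd.Series) -> pd.Series:
        x = g.to_numpy(float)
        n = x.size
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = stats.t.ppf(0.5 + conf_level / 2, n - 1) * sd / math.sqrt(n)
        else:
            half = 0.0
        return pd.Series(
            {
                "n": n,
                "mean": mean,
                "sd": sd,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
                "median": float(np.median(x)),
                "ci95_lo": mean - half,
                "ci95_hi": mean + half,
            }
        )

    keys = ["gender", "endpoint", "time", "group"]
    out = cage_table.groupby(keys, sort=False)["value"].apply(_one).unstack()
    out = out.reset_index()
    out["n"] = out["n"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Derived endpoints and screening
# ---------------------------------------------------------------------------


def feed_efficiency(weight_gain_g: float, feed_intake_g: float) -> float:
    """Feed efficiency in percent: weight gain [g] / feed intake [g] x 100.

    Negative gains (weight loss) are allowed; zero or negative intake is a
    domain error.
    """
    if feed_intake_g <= 0:
        raise DomainError(f"feed intake must be positive, got {feed_intake_g}")
    return 100.0 * weight_gain_g / feed_intake_g


def relative_organ_weight(organ_g: float, body_g: float) -> float:
    """Relative organ weight in percent: organ [g] / body weight [g] x 100."""
    if body_g <= 0:
        raise DomainError(f"body weight must be positive, got {body_g}")
    if organ_g < 0:
        raise DomainError(f"organ weight must be non-negative, got {organ_g}")
    return 100.0 * organ_g / body_g


def flag_extremes(values: Sequence[float] | pd.Series) -> list[ExtremeFlag]:
    """Screen values against Tukey fences Q1 - 1.5 IQR and Q3 + 1.5 IQR.

    Quartiles use linear interpolation between order statistics (type-7).
    Values are flagged, never removed.  Fewer than 4 finite values yield no
    flags with a warning.
    """
    if isinstance(values, pd.Series):
        index: Iterable = values.index
        arr = values.to_numpy(float)
    else:
        arr = np.asarray(list(values), float)
        index = range(arr.size)
    finite = np.isfinite(arr)
    if finite.sum() < 4:
        logger.warning("flag_extremes: fewer than 4 finite values, no screening done")
        return []
    q1, q3 = np.quantile(arr[finite], [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [
        ExtremeFlag(idx, float(v), float(lo), float(hi), bool(v < lo or v > hi))
        for idx, v in zip(index, arr)
    ]


def screen_extremes(cage_table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`flag_extremes` within every (group, gender, endpoint,
    time) cell of a table and return the rows with a ``flagged`` column."""
    keys = ["gender", "group", "endpoint", "time"]
    out = cage_table.copy()
    out["flagged"] = False
    for _, idx in out.groupby(keys, sort=False).groups.items():
        flags = flag_extremes(out.loc[idx, "value"])
        for f in flags:
            out.loc[f.index, "flagged"] = f.flagged
    return out


# ---------------------------------------------------------------------------
# Deterministic trial arithmetic
# ---------------------------------------------------------------------------


def dose_from_feed(conc_mg_per_kg_feed: float, intake_g_per_day: float, body_weight_g: float) -> float:
    """Ingested dose in mg per kg body weight per day.

    conc [mg/kg feed] x intake [g/day] is the daily intake in mg/1000;
    dividing by body weight in kg cancels the factor, leaving
    conc x intake / body_weight_g.
    """
    if body_weight_g <= 0:
        raise DomainError(f"body weight must be positive, got {body_weight_g}")
    if conc_mg_per_kg_feed < 0 or intake_g_per_day < 0:
        raise DomainError("concentration and intake must be non-negative")
    return conc_mg_per_kg_feed * intake_g_per_day / body_weight_g


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures with round-half-even ties."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(x))
    shift = d.adjusted() - (sig_figs - 1)
    q = d.scaleb(-shift).quantize(Decimal(1), rounding=ROUND_HALF_EVEN).scaleb(shift)
    return float(q)


def dose_ratio(level_33: float, level_11: float, sig_figs: int = 2) -> float:
    """Ratio of the high-inclusion to low-inclusion diet level, rounded to
    ``sig_figs`` significant figures (diet QC arithmetic)."""
    if level_11 <= 0:
        raise DomainError(f"denominator level must be positive, got {level_11}")
    return round_sig(level_33 / level_11, sig_figs)
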