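"""Feature-matrix assembly: daily aggregation, normalization, splitting.

The modeling table has a frozen column layout: 21 inputs (five raw weather
maxima, two psychrometric derivatives, the nine THI variants, and five
per-cow management fields) and 4 targets (milk yield, protein %, fat %,
concentrate intake), keyed by (cow_id, date).  All data are mapped to
[-1, 1] by a min-max normalizer fitted, by default, on the training rows
only; rows are divided 70/30 at random at the cow-day level.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd

from .thermal_indices import THI_INDICES, derive_weather_frame

logger = logging.getLogger(__name__)

__all__ = [
    "INPUT_COLUMNS",
    "TARGET_COLUMNS",
    "FeatureMatrix",
    "Normalizer",
    "SplitIndex",
    "aggregate_daily_max",
    "assemble_features",
    "split_rows",
]

#: The 21 model inputs, in frozen order.
INPUT_COLUMNS = [
    "temp_c",            # 1  daily max dry-bulb temperature
    "rh_pct",            # 2  daily max relative humidity
    "rain_mm",           # 3  daily rainfall total
    "wind_kmh",          # 4  daily max wind speed
    "wind_dir_deg",      # 5  wind direction at max speed
    "tdp_c",             # 6  dewpoint
    "twet_c",            # 7  wet-bulb
    *[f"thi{k}" for k in THI_INDICES],  # 8-16  THI variants 1-9
    "programmed_feed_kg",  # 17
    "lactation_days",      # 18
    "lactation_number",    # 19
    "milking_freq",        # 20
    "liveweight_kg",       # 21
]

#: The 4 model targets, in frozen order.
TARGET_COLUMNS = ["milk_yield_kg", "protein_pct", "fat_pct", "feed_intake_kg"]

KEY_COLUMNS = ["cow_id", "date"]


def aggregate_daily_max(intraday: pd.DataFrame, *, winddir_daily: str = "at-max-speed") -> pd.DataFrame:
    """Collapse intraday weather records to one row per calendar day.

    Temperature, relative humidity and wind speed take their daily maxima;
    rainfall, logged by the station as a daily running total, takes the
    final (= maximum) value of the day.  The daily wind direction is the
    direction observed at the maximum wind speed (ties broken by earliest
    timestamp); ``winddir_daily="literal-max"`` instead takes the maximum
    of the direction in degrees, reproducing a literal
    max-of-every-column reading.  Days with zero records are simply absent;
    a pressure column, when present, is averaged.
    """
    if winddir_daily not in ("at-max-speed", "literal-max"):
        raise ValueError(f"winddir_daily must be 'at-max-speed' or 'literal-max', got {winddir_daily!r}")
    if len(intraday) == 0:
        raise ValueError("no intraday records supplied")
    df = intraday.copy()
    ts = pd.to_datetime(df["date"])
    df["_day"] = ts.dt.date
    df["_ts"] = ts

    agg = {
        "temp_c": ("temp_c", "max"),
        "rh_pct": ("rh_pct", "max"),
        "rain_mm": ("rain_mm", "max"),  # running total: final == max
        "wind_kmh": ("wind_kmh", "max"),
    }
    if "pressure_kpa" in df.columns:
        agg["pressure_kpa"] = ("pressure_kpa", "mean")
    out = df.groupby("_day").agg(**agg)

    if winddir_daily == "literal-max":
        out["wind_dir_deg"] = df.groupby("_day")["wind_dir_deg"].max()
    else:
        # direction at max wind speed, earliest timestamp on ties
        def _dir_at_max(group: pd.DataFrame) -> float:
            peak = group["wind_kmh"].max()
            at_peak = group[group["wind_kmh"] == peak].sort_values("_ts")
            return float(at_peak["wind_dir_deg"].iloc[0])

        out["wind_dir_deg"] = (
            df.groupby("_day")[["wind_kmh", "wind_dir_deg", "_ts"]]
            .apply(_dir_at_max)
        )

    out = out.reset_index().rename(columns={"_day": "date"})
    cols = ["date", "temp_c", "rh_pct", "rain_mm", "wind_kmh", "wind_dir_deg"]
    if "pressure_kpa" in out.columns:
        cols.append("pressure_kpa")
    return out[cols]


@dataclasses.dataclass
class FeatureMatrix:
    """The assembled modeling table.

    ``inputs`` and ``targets`` share a RangeIndex aligned with ``keys``
    (cow_id, date).  ``n_dropped`` counts cow-day rows removed for missing
    values.  The column ``signature`` freezes the layout so a saved model
    can refuse a differently shaped matrix.
    """

    keys: pd.DataFrame
    inputs: pd.DataFrame
    targets: pd.DataFrame
    n_dropped: int = 0
    latent_targets: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.inputs.columns) != INPUT_COLUMNS:
            raise ValueError("inputs must carry exactly the 21 frozen input columns")
        if list(self.targets.columns) != TARGET_COLUMNS:
            raise ValueError("targets must carry exactly the 4 frozen target columns")
        if not (len(self.keys) == len(self.inputs) == len(self.targets)):
            raise ValueError("keys, inputs and targets must have equal row counts")

    @property
    def n_rows(self) -> int:
        return len(self.inputs)

    @property
    def signature(self) -> tuple[str, ...]:
        return tuple(INPUT_COLUMNS) + tuple(TARGET_COLUMNS)

    def to_frame(self) -> pd.DataFrame:
        """Single CSV-ready table: keys, 21 inputs, 4 targets in order."""
        return pd.concat(
            [self.keys.reset_index(drop=True),
             self.inputs.reset_index(drop=True),
             self.targets.reset_index(drop=True)],
            axis=1,
        )


def assemble_features(
    daily_weather: pd.DataFrame,
    cow_days: pd.DataFrame,
) -> FeatureMatrix:
    """Join derived daily weather onto cow-day records in the frozen layout.

    ``daily_weather`` may be raw (derived columns are computed) or already
    derived.  Every cow-day date must have a weather row; missing dates
    raise.  Rows with any missing input or target are dropped and counted.
    Rows with ``milking_freq == 0`` (and hence zero yield) are retained —
    zero is a legitimate target value under voluntary milking.
    """
    if "thi9" not in daily_weather.columns:
        daily_weather = derive_weather_frame(daily_weather)

    weather = daily_weather.copy()
    weather["date"] = pd.to_datetime(weather["date"]).dt.date
    cows = cow_days.copy()
    cows["date"] = pd.to_datetime(cows["date"]).dt.date

    missing_dates = sorted(set(cows["date"]) - set(weather["date"]))
    if missing_dates:
        raise ValueError(
            f"{len(missing_dates)} cow-day dates lack weather rows, "
            f"first few: {missing_dates[:5]}"
        )

    weather_cols = [c for c in INPUT_COLUMNS if c in weather.columns]
    merged = cows.merge(weather[["date", *weather_cols]], on="date", how="left")

    needed = INPUT_COLUMNS + TARGET_COLUMNS
    complete = merged[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d cow-day rows with missing values", n_dropped)
    kept = merged[complete]
    # row key order is canonical: sort by (cow_id, date) so assembly is
    # invariant to input row permutation
    kept = kept.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)

    latent = None
    latent_cols = [f"latent_{c}" for c in TARGET_COLUMNS]
    if all(c in kept.columns for c in latent_cols):
        latent = kept[latent_cols].copy()

    return FeatureMatrix(
        keys=kept[KEY_COLUMNS].copy(),
        inputs=kept[INPUT_COLUMNS].astype(float).copy(),
        targets=kept[TARGET_COLUMNS].astype(float).copy(),
        n_dropped=n_dropped,
        latent_targets=latent,
    )


@dataclasses.dataclass
class Normalizer:
    """Per-column min-max map onto [-1, 1].

    ``apply`` sends the fitted minimum to -1 and maximum to +1; values
    outside the fitted range (e.g. test rows beyond the training envelope)
    map outside [-1, 1] and are deliberately not clipped.  ``invert``
    restores original units exactly (round trip < 1e-12).
    """

    columns: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame, rows=None) -> "Normalizer":
        """Fit column ranges on ``rows`` (default: all rows)."""
        sub = table if rows is None else table.iloc[rows]
        if len(sub) == 0:
            raise ValueError("cannot fit a normalizer on zero rows")
        mins = sub.min(axis=0).to_numpy(dtype=float)
        maxs = sub.max(axis=0).to_numpy(dtype=float)
        constant = np.flatnonzero(maxs <= mins)
        if constant.size:
            names = [table.columns[i] for i in constant]
            raise ValueError(f"constant column(s) cannot be normalized: {names}")
        return cls(columns=list(table.columns), mins=mins, maxs=maxs)

    def _check(self, table: pd.DataFrame) -> None:
        if list(table.columns) != self.columns:
            raise ValueError(
                f"column signature mismatch: fitted {self.columns}, got {list(table.columns)}"
            )

    def apply(self, table: pd.DataFrame) -> np.ndarray:
        self._check(table)
        x = table.to_numpy(dtype=float)
        return 2.0 * (x - self.mins) / (self.maxs - self.mins) - 1.0

    def invert(self, normalized: np.ndarray) -> pd.DataFrame:
        x = np.asarray(normalized, dtype=float)
        orig = (x + 1.0) / 2.0 * (self.maxs - self.mins) + self.mins
        return pd.DataFrame(orig, columns=self.columns)

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            columns=list(d["columns"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
        )


@dataclasses.dataclass
class SplitIndex:
    """Random 70/30 (by default) row division into training and testing."""

    train: np.ndarray
    test: np.ndarray
    seed: int
    fraction: float

    @property
    def n(self) -> int:
        return len(self.train) + len(self.test)

    def to_dict(self) -> dict:
        return {
            "train": self.train.tolist(),
            "test": self.test.tolist(),
            "seed": self.seed,
            "fraction": self.fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitIndex":
        return cls(
            train=np.asarray(d["train"], dtype=int),
            test=np.asarray(d["test"], dtype=int),
            seed=int(d["seed"]),
            fraction=float(d["fraction"]),
        )


def split_rows(n: int, fraction: float = 0.7, seed: int = 0) -> SplitIndex:
    """Uniform random row split; ``|train| = round(fraction * n)``.

    The split is over cow-day rows, not cows, so the same cow can appear in
    both partitions on different days.
    """
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction!r}")
    n_train = int(np.rint(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"fraction {fraction} of {n} rows leaves an empty partition"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndex(
        train=np.sort(perm[:n_train]),
        test=np.sort(perm[n_train:]),
        seed=seed,
        fraction=fraction,
    )


def save_sidecar(path, normalizer_x: Normalizer, normalizer_t: Normalizer, split: SplitIndex) -> None:
    """Persist the normalizers and split for exact reproducibility."""
    with open(path, "w") as fh:
        json.dump(
            {
                "input_normalizer": normalizer_x.to_dict(),
                "target_normalizer": normalizer_t.to_dict(),
                "split": split.to_dict(),
            },
            fh,
        )
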