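"""Model evaluation surface: pooled fit metrics, outliers, seasonal means.

The reporting convention pools the four normalized targets into a single
stream of observations, so each stage (training / testing / overall) gets
one correlation coefficient R, one regression slope b (from the
least-squares fit of observed on predicted), and one mean squared error —
with observation counts equal to samples x 4.  Outliers are observations
outside the two-sided 95% prediction interval of the observed-vs-predicted
regression line.  Seasonal summaries average THI9 and the four targets per
meteorological season and year.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .brann import TrainedModel
from .dataset import FeatureMatrix, SplitIndex, TARGET_COLUMNS

__all__ = [
    "FitReport",
    "StageMetrics",
    "regression_metrics",
    "outlier_fraction",
    "build_report",
    "seasonal_summary",
]


def regression_metrics(pred, obs) -> tuple[float, float, float]:
    """Pooled (R, b, MSE) between predictions and observations.

    Both arrays are flattened, pooling targets when 2-D.  R is the Pearson
    correlation; b the slope of the least-squares line ``obs = b*pred + a``;
    MSE the mean squared difference.  All three live on whatever scale the
    inputs are on (normalized, for stage reports).
    """
    p = np.asarray(pred, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError("pred and obs must have identical shapes")
    if p.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(p) == 0.0 or np.ptp(o) == 0.0:
        raise ValueError("zero variance in pred or obs")
    r = float(np.corrcoef(p, o)[0, 1])
    pc = p - p.mean()
    b = float((pc @ (o - o.mean())) / (pc @ pc))
    mse = float(np.mean((o - p) ** 2))
    return r, b, mse


def outlier_fraction(pred, obs, level: float = 0.95, *, bounds: str = "prediction") -> tuple[int, float]:
    """Count observations outside the two-sided ``level`` bounds of the
    observed-on-predicted regression.

    Fits ``obs = b*pred + a`` by least squares and computes, at each
    prediction x, the interval half-width

        t_{n-2, (1+level)/2} * s * sqrt(w + 1/n + (x - xbar)^2 / Sxx)

    with ``w = 1`` for a prediction interval (default — each observation is
    judged against the scatter of new observations, which is what yields
    per-observation outlier counts) or ``w = 0`` for a confidence interval
    on the fitted mean (``bounds="confidence"``).

    Returns ``(count, percent)`` with ``percent = 100 * count / n``.
    """
    if bounds not in ("prediction", "confidence"):
        raise ValueError(f"bounds must be 'prediction' or 'confidence', got {bounds!r}")
    p = np.asarray(pred, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    n = p.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(p) == 0.0:
        raise ValueError("degenerate fit: zero variance in pred")
    xbar = p.mean()
    sxx = float(np.sum((p - xbar) ** 2))
    b = float(np.sum((p - xbar) * (o - o.mean())) / sxx)
    a = float(o.mean() - b * xbar)
    resid = o - (a + b * p)
    s2 = float(resid @ resid) / (n - 2)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 2)
    w = 1.0 if bounds == "prediction" else 0.0
    half = tcrit * np.sqrt(s2 * (w + 1.0 / n + (p - xbar) ** 2 / sxx))
    count = int(np.sum(np.abs(resid) > half))
    return count, 100.0 * count / n


@dataclasses.dataclass
class StageMetrics:
    """One stage's row of the fit report."""

    stage: str
    samples: int
    observations: int
    r: float
    b: float
    mse: float

    def __post_init__(self) -> None:
        if self.observations != 4 * self.samples:
            raise ValueError("observations must equal 4 x samples")


@dataclasses.dataclass
class FitReport:
    """Training / testing / overall metrics plus 95%-bound outliers.

    ``per_target`` holds supplementary per-target test metrics including
    de-normalized RMSE in original units.
    """

    stages: list[StageMetrics]
    outlier_count: int
    outlier_percent: float
    per_target: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.stages])


def build_report(
    model: TrainedModel,
    features: FeatureMatrix,
    split: SplitIndex,
    *,
    bounds: str = "prediction",
) -> FitReport:
    """Evaluate a trained model on its feature matrix, stage by stage.

    Metrics are computed on the normalized scale (so MSE magnitudes are
    comparable across targets); outliers are counted on the pooled overall
    stage.  Per-target test RMSEs are also reported in original units.
    """
    if tuple(model.params.signature) != tuple(features.signature):
        raise ValueError("feature-matrix signature does not match the trained model")
    x = model.input_normalizer.apply(features.inputs)
    t = model.target_normalizer.apply(features.targets)
    y = model.predict_normalized(x)

    stages = []
    for name, rows in (
        ("training", split.train),
        ("testing", split.test),
        ("overall", np.concatenate([split.train, split.test])),
    ):
        r, b, mse = regression_metrics(y[rows], t[rows])
        stages.append(
            StageMetrics(
                stage=name, samples=len(rows), observations=4 * len(rows),
                r=r, b=b, mse=mse,
            )
        )

    count, percent = outlier_fraction(y, t, 0.95, bounds=bounds)

    rows = split.test
    resid_orig = (
        model.target_normalizer.invert(y[rows]).to_numpy()
        - features.targets.iloc[rows].to_numpy()
    )
    per_target = []
    for j, col in enumerate(TARGET_COLUMNS):
        r_j, b_j, mse_j = regression_metrics(y[rows][:, j], t[rows][:, j])
        per_target.append(
            {
                "target": col, "r": r_j, "b": b_j, "mse_normalized": mse_j,
                "rmse_original_units": float(np.sqrt(np.mean(resid_orig[:, j] ** 2))),
            }
        )
    return FitReport(
        stages=stages,
        outlier_count=count,
        outlier_percent=percent,
        per_target=pd.DataFrame(per_target),
    )


def noise_ceiling_r(features: FeatureMatrix, target_normalizer, rows=None) -> float:
    """Pooled correlation between observed and latent (noiseless) targets.

    This is the generative upper bound on any model's pooled R: no
    predictor of the latent response can correlate with the observations
    better than the latent response itself.  Requires a feature matrix
    assembled from simulation output that kept its ``latent_*`` columns.
    """
    if features.latent_targets is None:
        raise ValueError("feature matrix carries no latent target columns")
    t_norm = target_normalizer.apply(features.targets)
    lat = features.latent_targets.to_numpy(dtype=float)
    lat_norm = (
        2.0 * (lat - target_normalizer.mins)
        / (target_normalizer.maxs - target_normalizer.mins)
        - 1.0
    )
    if rows is not None:
        t_norm, lat_norm = t_norm[rows], lat_norm[rows]
    r, _, _ = regression_metrics(lat_norm, t_norm)
    return r


_SEASONS_SOUTH = {12: "summer", 1: "summer", 2: "summer",
                  3: "autumn", 4: "autumn", 5: "autumn",
                  6: "winter", 7: "winter", 8: "winter",
                  9: "spring", 10: "spring", 11: "spring"}
_SEASONS_NORTH = {12: "winter", 1: "winter", 2: "winter",
                  3: "spring", 4: "spring", 5: "spring",
                  6: "summer", 7: "summer", 8: "summer",
                  9: "autumn", 10: "autumn", 11: "autumn"}


def seasonal_summary(
    cow_days: pd.DataFrame,
    derived_weather: pd.DataFrame,
    hemisphere: str = "south",
) -> pd.DataFrame:
    """Mean THI9 and the four targets per meteorological season and year.

    Seasons are the standard three-month meteorological blocks; December is
    assigned to the season-year of the following January (a Southern
    summer labelled 2018 spans Dec 2017 - Feb 2018).  Only non-empty
    season-year groups appear.
    """
    if hemisphere not in ("south", "north"):
        raise ValueError(f"hemisphere must be 'south' or 'north', got {hemisphere!r}")
    season_map = _SEASONS_SOUTH if hemisphere == "south" else _SEASONS_NORTH

    weather = derived_weather.copy()
    weather["date"] = pd.to_datetime(weather["date"]).dt.date
    cows = cow_days.copy()
    cows["date"] = pd.to_datetime(cows["date"]).dt.date
    merged = cows.merge(weather[["date", "thi9"]], on="date", how="inner")

    ts = pd.to_datetime(merged["date"])
    merged["season"] = ts.dt.month.map(season_map)
    merged["season_year"] = ts.dt.year + (ts.dt.month == 12).astype(int)

    grouped = (
        merged.groupby(["season_year", "season"], as_index=False)
        .agg(
            mean_thi9=("thi9", "mean"),
            mean_milk_yield_kg=("milk_yield_kg", "mean"),
            mean_protein_pct=("protein_pct", "mean"),
            mean_fat_pct=("fat_pct", "mean"),
            mean_feed_intake_kg=("feed_intake_kg", "mean"),
            n_cow_days=("thi9", "size"),
        )
        .sort_values(["season_year", "season"])
        .reset_index(drop=True)
    )
    return grouped
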