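"""Seeded synthetic robotic-dairy-farm generator.

Real automated-milking-system (AMS) records are proprietary, so this module
provides a fully specified generative model of a temperate pasture-based
robotic dairy: daily-maximum weather with Southern-Hemisphere seasonality,
a herd with genomic heat-tolerance breeding values, and per-cow-day
production records driven by a Wood lactation curve with a linear
heat-stress decrement above a THI threshold.

Because the generative response is known exactly (latent noiseless targets
are stored alongside the noisy observations), downstream feature
engineering, network training, evaluation and drafting logic can be tested
for parameter recovery rather than against withheld farm data.

All randomness flows through a single integer seed per parameter block;
identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Sequence

import numpy as np
import pandas as pd

from .thermal_indices import derive_weather_frame

__all__ = [
    "WeatherSimParams",
    "CowAttributes",
    "ResponseParams",
    "generate_weather",
    "generate_herd",
    "generate_cow_days",
    "COW_DAY_COLUMNS",
    "LATENT_COLUMNS",
    "tolerance_scale",
    "wood_curve",
]

#: Cow-day table column order (observed part).
COW_DAY_COLUMNS = [
    "cow_id", "date", "programmed_feed_kg", "lactation_days",
    "lactation_number", "milking_freq", "liveweight_kg",
    "milk_yield_kg", "protein_pct", "fat_pct", "feed_intake_kg",
]

#: Noiseless generative values of the four targets (simulation only).
LATENT_COLUMNS = [
    "latent_milk_yield_kg", "latent_protein_pct",
    "latent_fat_pct", "latent_feed_intake_kg",
]


@dataclasses.dataclass
class WeatherSimParams:
    """Parameters of the daily-maximum weather simulator.

    The temperature series is a seasonal cosine plus an AR(1) anomaly;
    relative humidity is anti-phased with temperature (dry hot summers);
    rainfall is a Bernoulli-gamma mixture and wind speed a gamma draw.
    Defaults emulate a northern-Victoria station: winter daily maxima
    around 14 degC, summer around 31 degC with heatwave excursions above
    40 degC, daily-maximum RH near saturation in winter.

    ``phase_day`` is the day-of-year of peak temperature (mid-January for
    the Southern Hemisphere).
    """

    t_mean_c: float = 21.3
    t_amplitude_c: float = 6.8
    t_ar1: float = 0.62
    t_innovation_sd: float = 3.0
    phase_day: float = 15.0
    rh_base_pct: float = 78.0
    rh_seasonal_amplitude_pct: float = 18.0
    rh_temp_slope: float = -1.6     # % RH per degC of temperature anomaly
    rh_noise_sd: float = 5.0
    rain_wet_prob: float = 0.30
    rain_gamma_shape: float = 0.65
    rain_gamma_scale_mm: float = 9.0
    wind_gamma_shape: float = 9.0
    wind_gamma_scale_kmh: float = 1.8
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if not 0.0 <= self.t_ar1 < 1.0:
            bad.append("t_ar1 must be in [0, 1)")
        if self.t_innovation_sd < 0:
            bad.append("t_innovation_sd must be >= 0")
        if self.rh_noise_sd < 0:
            bad.append("rh_noise_sd must be >= 0")
        if not 0.0 <= self.rain_wet_prob <= 1.0:
            bad.append("rain_wet_prob must be in [0, 1]")
        if self.rain_gamma_shape <= 0 or self.rain_gamma_scale_mm <= 0:
            bad.append("rain gamma parameters must be > 0")
        if self.wind_gamma_shape <= 0 or self.wind_gamma_scale_kmh <= 0:
            bad.append("wind gamma parameters must be > 0")
        if bad:
            raise ValueError("invalid WeatherSimParams: " + "; ".join(bad))


@dataclasses.dataclass(frozen=True)
class CowAttributes:
    """Static attributes of one cow.

    ``heat_tolerance_bv`` is the genomic heat-tolerance breeding value,
    centred at 100: a cow at 93 is 7% less heat tolerant than average, one
    at 110 is 10% more tolerant.
    """

    cow_id: str
    heat_tolerance_bv: float
    lactation_number: int
    calving_date: _dt.date
    base_liveweight_kg: float
    lactation_length_days: int = 365

    def __post_init__(self) -> None:
        if self.heat_tolerance_bv <= 0:
            raise ValueError("heat_tolerance_bv must be > 0")
        if self.lactation_number < 1:
            raise ValueError("lactation_number must be >= 1")


@dataclasses.dataclass
class ResponseParams:
    """Generative response linking weather and cow state to the four targets.

    Milk yield follows a Wood curve ``A * t^b * exp(-c*t)`` over lactation
    days, scaled by parity, and reduced linearly by ``k_yield`` per THI9
    unit above ``thi_threshold``, with the reduction scaled by the cow's
    heat-tolerance factor ``s(bv) = 1 - (bv - 100)/100`` (so low breeding
    values suffer more).  Protein falls mildly with THI9; fat is diluted by
    yield.  Concentrate intake is the programmed allocation times an
    appetite factor, depressed by ``k_intake`` per THI9 unit above
    threshold.  Observed values are latent values plus Gaussian noise,
    clipped at zero; zero-milking days have exactly zero yield.
    """

    wood_a: float = 21.0
    wood_b: float = 0.20
    wood_c: float = 0.004
    thi_threshold: float = 72.0       # on THI9
    k_yield: float = 0.018            # fractional yield loss per THI9 unit above threshold
    k_intake: float = 0.012
    parity1_scale: float = 0.85       # first-lactation yield scaling
    protein_base_pct: float = 3.55
    protein_thi_slope: float = -0.010  # % protein per THI9 unit above 50
    protein_seasonal_amplitude_pct: float = 0.0
    fat_base_pct: float = 4.75
    fat_yield_dilution: float = -0.020  # % fat per kg/day of latent yield
    fat_seasonal_amplitude_pct: float = 0.0
    appetite: float = 0.92            # fraction of programmed feed consumed when cool
    noise_sd_yield: float = 2.2
    noise_sd_protein: float = 0.16
    noise_sd_fat: float = 0.32
    noise_sd_intake: float = 0.55
    zero_milking_prob: float = 0.02   # voluntary-system days with no milking visit
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.wood_a < 0 or self.k_yield < 0 or self.k_intake < 0:
            bad.append("wood_a, k_yield, k_intake must be >= 0")
        for f in ("noise_sd_yield", "noise_sd_protein", "noise_sd_fat", "noise_sd_intake"):
            if getattr(self, f) < 0:
                bad.append(f"{f} must be >= 0")
        if not 0.0 <= self.zero_milking_prob < 1.0:
            bad.append("zero_milking_prob must be in [0, 1)")
        if bad:
            raise ValueError("invalid ResponseParams: " + "; ".join(bad))


def wood_curve(t_days, a: float, b: float, c: float):
    """Wood lactation curve y(t) = A * t^b * exp(-c t), kg/day, y(0) = 0."""
    t = np.asarray(t_days, dtype=float)
    with np.errstate(invalid="ignore"):
        y = a * np.power(np.maximum(t, 0.0), b) * np.exp(-c * np.maximum(t, 0.0))
    return np.where(t <= 0, 0.0, y)


def tolerance_scale(bv):
    """Heat-stress susceptibility factor s(bv) = 1 - (bv - 100)/100.

    A breeding value of 93 gives 1.07 (7% stronger decrement than average);
    110 gives 0.90 (10% weaker).
    """
    return 1.0 - (np.asarray(bv, dtype=float) - 100.0) / 100.0


def generate_weather(
    n_days: int,
    params: WeatherSimParams | None = None,
    start_date: _dt.date = _dt.date(2016, 6, 1),
) -> pd.DataFrame:
    """Generate ``n_days`` of daily-maximum weather records.

    Returns a DataFrame with the raw weather columns ``date, temp_c,
    rh_pct, rain_mm, wind_kmh, wind_dir_deg``.  Temperature is clipped to
    [-5, 48] degC and RH to (5, 100]; the seasonal phase makes summer
    (around ``phase_day``) hotter than winter by construction.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    params = params or WeatherSimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    dates = pd.date_range(start_date, periods=n_days, freq="D")
    doy = dates.day_of_year.to_numpy(dtype=float)
    seasonal = params.t_amplitude_c * np.cos(
        2.0 * np.pi * (doy - params.phase_day) / 365.25
    )

    # AR(1) temperature anomaly, stationary start.
    anom = np.empty(n_days)
    sd0 = params.t_innovation_sd / max(np.sqrt(1.0 - params.t_ar1**2), 1e-12)
    anom[0] = rng.normal(0.0, sd0) if params.t_innovation_sd > 0 else 0.0
    innov = rng.normal(0.0, params.t_innovation_sd, size=n_days)
    for i in range(1, n_days):
        anom[i] = params.t_ar1 * anom[i - 1] + innov[i]
    temp = np.clip(params.t_mean_c + seasonal + anom, -5.0, 48.0)

    # RH anti-phased with the temperature seasonal cycle and anomaly.
    rh = (
        params.rh_base_pct
        - params.rh_seasonal_amplitude_pct
        * np.cos(2.0 * np.pi * (doy - params.phase_day) / 365.25)
        + params.rh_temp_slope * anom
        + rng.normal(0.0, params.rh_noise_sd, size=n_days)
    )
    rh = np.clip(rh, 5.0 + 1e-9, 100.0)

    wet = rng.random(n_days) < params.rain_wet_prob
    rain = np.where(
        wet,
        rng.gamma(params.rain_gamma_shape, params.rain_gamma_scale_mm, size=n_days),
        0.0,
    )
    wind = rng.gamma(params.wind_gamma_shape, params.wind_gamma_scale_kmh, size=n_days)
    wind_dir = rng.uniform(0.0, 360.0, size=n_days)

    return pd.DataFrame(
        {
            "date": dates.date,
            "temp_c": temp,
            "rh_pct": rh,
            "rain_mm": rain,
            "wind_kmh": wind,
            "wind_dir_deg": wind_dir,
        }
    )


def generate_herd(
    n_cows: int,
    bv_range: tuple[float, float] = (93.0, 112.0),
    seed: int = 0,
    start_date: _dt.date = _dt.date(2016, 6, 1),
    extended_lactation_fraction: float = 0.10,
) -> list[CowAttributes]:
    """Generate a herd of ``n_cows`` with staggered calvings.

    Breeding values are uniform on ``bv_range`` (the default span matches a
    herd selected for similar heat tolerance, 93-112).  Lactation numbers
    are drawn 1-8 with a realistic decay toward high parities.  Calving
    dates are staggered through the year before ``start_date`` so the herd
    covers all lactation stages.  A configurable fraction of cows are
    'carryover' animals with extended (>600 day) lactations.
    """
    if n_cows < 1:
        raise ValueError("n_cows must be >= 1")
    lo, hi = bv_range
    if not (lo <= hi):
        raise ValueError(f"empty breeding-value range {bv_range!r}")
    rng = np.random.default_rng(seed)
    bvs = rng.uniform(lo, hi, size=n_cows)
    parity_probs = np.array([0.28, 0.24, 0.18, 0.12, 0.08, 0.05, 0.03, 0.02])
    parities = rng.choice(np.arange(1, 9), size=n_cows, p=parity_probs)
    offsets = rng.integers(0, 365, size=n_cows)  # days before start_date
    weights = rng.normal(660.0, 70.0, size=n_cows).clip(380.0, 950.0)
    extended = rng.random(n_cows) < extended_lactation_fraction
    lengths = np.where(extended, rng.integers(620, 760, size=n_cows),
                       rng.integers(330, 420, size=n_cows))
    herd = []
    for i in range(n_cows):
        herd.append(
            CowAttributes(
                cow_id=f"cow{i + 1:04d}",
                heat_tolerance_bv=float(bvs[i]),
                lactation_number=int(parities[i]),
                calving_date=start_date - _dt.timedelta(days=int(offsets[i])),
                base_liveweight_kg=float(weights[i]),
                lactation_length_days=int(lengths[i]),
            )
        )
    return herd


DRY_PERIOD_DAYS = 60


def generate_cow_days(
    weather: pd.DataFrame,
    herd: Sequence[CowAttributes],
    params: ResponseParams | None = None,
    *,
    keep_latent: bool = True,
) -> pd.DataFrame:
    """Simulate per-cow-day management records and the four targets.

    ``weather`` must be a daily table already carrying the derived
    columns (``thi9`` in particular); raw tables are derived on the fly.
    Each cow cycles: lactation of ``lactation_length_days`` days, then a
    dry period (no milking, zero yield and programmed feed), then a new
    calving incrementing the lactation number.

    Latent (noiseless) target values are stored in ``latent_*`` columns
    when ``keep_latent`` (the default) so that downstream evaluation can
    compute a generative noise ceiling.
    """
    if len(herd) == 0:
        raise ValueError("herd must be non-empty")
    params = params or ResponseParams()
    params.validate()
    if "thi9" not in weather.columns:
        weather = derive_weather_frame(weather)

    rng = np.random.default_rng(params.seed)
    n_days = len(weather)
    dates = pd.to_datetime(weather["date"]).dt.date.to_numpy()
    thi9 = weather["thi9"].to_numpy(dtype=float)
    excess = np.maximum(0.0, thi9 - params.thi_threshold)
    doy = pd.to_datetime(weather["date"]).dt.day_of_year.to_numpy(dtype=float)
    seasonal = np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)  # summer-peaking (SH)

    frames = []
    for cow in herd:
        s_bv = float(tolerance_scale(cow.heat_tolerance_bv))
        days_since_calving = np.array(
            [(d - cow.calving_date).days for d in dates], dtype=int
        )

        # Roll lactations forward: each cycle = lactation + dry period.
        cycle = cow.lactation_length_days + DRY_PERIOD_DAYS
        n_cycles = days_since_calving // cycle
        lact_days = days_since_calving - n_cycles * cycle
        in_dry = lact_days >= cow.lactation_length_days
        lact_no = np.clip(cow.lactation_number + n_cycles, 1, None)

        parity_scale = np.where(lact_no == 1, params.parity1_scale,
                                1.0 + 0.02 * np.minimum(lact_no - 2, 2))

        milking = ~in_dry & (rng.random(n_days) >= params.zero_milking_prob)
        freq = np.where(
            milking, np.clip(rng.poisson(2.4, size=n_days), 1, 6), 0
        )

        base_yield = wood_curve(lact_days, params.wood_a, params.wood_b, params.wood_c)
        heat_factor = np.maximum(0.0, 1.0 - params.k_yield * s_bv * excess)
        latent_yield = np.where(
            freq > 0, base_yield * parity_scale * heat_factor, 0.0
        )

        latent_protein = (
            params.protein_base_pct
            + params.protein_thi_slope * np.maximum(0.0, thi9 - 50.0)
            + params.protein_seasonal_amplitude_pct * seasonal
        )
        latent_fat = (
            params.fat_base_pct
            + params.fat_yield_dilution * latent_yield
            + params.fat_seasonal_amplitude_pct * seasonal
        )

        # Programmed concentrate: higher in early lactation, zero when dry.
        programmed = np.where(
            in_dry, 0.0,
            np.clip(9.5 - 0.006 * np.maximum(lact_days - 60, 0)
                    + rng.normal(0.0, 1.2, size=n_days), 0.0, 16.0),
        ).round(1)
        latent_intake = programmed * params.appetite * np.maximum(
            0.0, 1.0 - params.k_intake * s_bv * excess
        )
        latent_intake = np.where(freq > 0, latent_intake, 0.0)

        obs_yield = np.where(
            freq > 0,
            np.maximum(0.0, latent_yield + rng.normal(0.0, params.noise_sd_yield, n_days)),
            0.0,
        )
        obs_protein = np.maximum(
            0.1, latent_protein + rng.normal(0.0, params.noise_sd_protein, n_days)
        )
        obs_fat = np.maximum(
            0.1, latent_fat + rng.normal(0.0, params.noise_sd_fat, n_days)
        )
        obs_intake = np.where(
            freq > 0,
            np.clip(latent_intake + rng.normal(0.0, params.noise_sd_intake, n_days),
                    0.0, programmed + 0.5),
            0.0,
        )

        liveweight = np.clip(
            cow.base_liveweight_kg
            + 12.0 * (lact_no - cow.lactation_number)     # mature-weight gain
            - 25.0 * np.exp(-np.maximum(lact_days, 0) / 90.0)  # post-calving dip
            + rng.normal(0.0, 6.0, size=n_days),
            330.0, 960.0,
        )

        frame = pd.DataFrame(
            {
                "cow_id": cow.cow_id,
                "date": dates,
                "programmed_feed_kg": programmed,
                "lactation_days": lact_days,
                "lactation_number": lact_no,
                "milking_freq": freq,
                "liveweight_kg": liveweight.round(1),
                "milk_yield_kg": obs_yield.round(2),
                "protein_pct": obs_protein.round(2),
                "fat_pct": obs_fat.round(2),
                "feed_intake_kg": obs_intake.round(2),
            }
        )
        if keep_latent:
            frame["latent_milk_yield_kg"] = latent_yield
            frame["latent_protein_pct"] = latent_protein
            frame["latent_fat_pct"] = latent_fat
            frame["latent_feed_intake_kg"] = latent_intake
        frames.append(frame)

    return pd.concat(frames, ignore_index=True)
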