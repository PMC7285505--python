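"""Psychrometric derivations and the temperature-humidity index (THI) family.

Heat load on dairy cattle is conventionally summarised by a
temperature-humidity index.  Many variants coexist in the animal
biometeorology literature, differing in which psychrometric quantity
(wet-bulb, dewpoint, relative humidity) carries the moisture signal and in
their empirical weights.  This module computes dewpoint temperature from the
Magnus approximation, wet-bulb temperature by bisection on the psychrometer
balance, and nine published THI variants, for single records or whole daily
weather tables.

Units: temperatures in degC, relative humidity in percent, pressure in kPa,
THI dimensionless (Fahrenheit-like scale).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAGNUS_A",
    "MAGNUS_B",
    "PSYCHROMETER_COEFF",
    "STANDARD_PRESSURE_KPA",
    "WeatherRecord",
    "DerivedWeather",
    "dewpoint_c",
    "saturation_vapor_pressure_hpa",
    "wet_bulb_c",
    "thi",
    "thi_all",
    "derive_weather",
    "derive_weather_frame",
]

# Magnus saturation-vapor-pressure constants (reference 6.112 hPa over water).
MAGNUS_A = 17.67
MAGNUS_B = 243.5  # degC
MAGNUS_E0_HPA = 6.112

#: Psychrometer coefficient for an unventilated instrument, K^-1.
PSYCHROMETER_COEFF = 6.6e-4

#: Default surface pressure when a station does not report it, kPa.
STANDARD_PRESSURE_KPA = 101.325

#: Absolute bisection tolerance for the wet-bulb solve, degC.
WET_BULB_TOL_C = 1e-3
WET_BULB_MAX_ITER = 100

#: Valid THI variant indices.
THI_INDICES = tuple(range(1, 10))

#: Which psychrometric argument each THI variant requires besides T.
_THI_NEEDS = {
    1: "twet", 2: "twet", 3: "twet", 4: "twet",
    5: "rh", 6: "tdp", 7: "tdp", 8: "rh", 9: "rh",
}


@dataclasses.dataclass(frozen=True)
class WeatherRecord:
    """One day (or one timestamp) of raw station weather.

    Parameters
    ----------
    date : datetime.date or datetime.datetime
        Calendar day, or timestamp for intraday records.
    temp_c : float
        Dry-bulb air temperature, degC.
    rh_pct : float
        Relative humidity, percent, in (0, 100].
    rain_mm : float
        Rainfall, mm (daily total, or running total for intraday records).
    wind_kmh : float
        Wind speed, km/h, >= 0.
    wind_dir_deg : float
        Wind direction, degrees in [0, 360].
    pressure_kpa : float, optional
        Surface pressure, kPa; defaults to the standard atmosphere.
    """

    date: _dt.date
    temp_c: float
    rh_pct: float
    rain_mm: float = 0.0
    wind_kmh: float = 0.0
    wind_dir_deg: float = 0.0
    pressure_kpa: float = STANDARD_PRESSURE_KPA

    def __post_init__(self) -> None:
        if not 0.0 < self.rh_pct <= 100.0:
            raise ValueError(
                f"rh_pct must be in (0, 100], got {self.rh_pct!r} on {self.date}"
            )
        if self.pressure_kpa <= 0:
            raise ValueError(
                f"pressure_kpa must be > 0, got {self.pressure_kpa!r} on {self.date}"
            )
        if not 0.0 <= self.wind_dir_deg <= 360.0:
            raise ValueError(
                f"wind_dir_deg must be in [0, 360], got {self.wind_dir_deg!r} "
                f"on {self.date}"
            )
        if self.wind_kmh < 0:
            raise ValueError(
                f"wind_kmh must be >= 0, got {self.wind_kmh!r} on {self.date}"
            )
        if self.rain_mm < 0:
            raise ValueError(
                f"rain_mm must be >= 0, got {self.rain_mm!r} on {self.date}"
            )


@dataclasses.dataclass(frozen=True)
class DerivedWeather:
    """Psychrometric derivatives of one weather record.

    ``thi`` holds the nine index values; ``thi[k - 1]`` is variant ``k``.
    Invariant: ``tdp_c <= twet_c <= temp_c`` (to solver tolerance), with
    equality at 100% relative humidity.
    """

    date: _dt.date
    tdp_c: float
    twet_c: float
    thi: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.thi) != 9:
            raise ValueError("thi must hold exactly nine values")


def saturation_vapor_pressure_hpa(t_c):
    """Magnus saturation vapor pressure over water, hPa, at temperature degC."""
    t_c = np.asarray(t_c, dtype=float)
    return MAGNUS_E0_HPA * np.exp(MAGNUS_A * t_c / (MAGNUS_B + t_c))


def dewpoint_c(temp_c, rh_pct):
    """Dewpoint temperature (degC) from the Magnus approximation.

    Inverts the Magnus saturation curve at the ambient vapor pressure:

        gamma = A*T/(B + T) + ln(RH/100),   Tdp = B*gamma / (A - gamma)

    with A = 17.67 and B = 243.5 degC.  At RH = 100 the log term vanishes
    and the dewpoint equals the dry-bulb temperature.

    Parameters
    ----------
    temp_c : float or array_like
        Dry-bulb temperature, degC (must exceed -243.5).
    rh_pct : float or array_like
        Relative humidity, percent, in (0, 100].

    Returns
    -------
    float or ndarray
        Dewpoint temperature, degC; always <= ``temp_c``.
    """
    t = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh <= 0.0) or np.any(rh > 100.0):
        raise ValueError(f"relative humidity must be in (0, 100], got {rh_pct!r}")
    if np.any(t <= -MAGNUS_B):
        raise ValueError(f"temperature must exceed {-MAGNUS_B} degC, got {temp_c!r}")
    gamma = MAGNUS_A * t / (MAGNUS_B + t) + np.log(rh / 100.0)
    out = MAGNUS_B * gamma / (MAGNUS_A - gamma)
    if out.ndim == 0:
        return float(out)
    return out


def wet_bulb_c(temp_c, tdp_c, pressure_kpa=STANDARD_PRESSURE_KPA):
    """Wet-bulb temperature (degC) by bisection on the psychrometer balance.

    Solves for the root Twet of

        e(Tdp) = es(Twet) - A * P * (T - Twet)

    on the bracket [Tdp, T], where ``es`` is the Magnus saturation curve
    (hPa), ``e(Tdp) = es(Tdp)`` is the ambient vapor pressure, P is surface
    pressure (hPa) and A is the psychrometer coefficient for an unventilated
    instrument (6.6e-4 K^-1).  The balance is monotone in Twet, so bisection
    converges unconditionally; iteration stops at 0.001 degC.

    Accepts scalars or equal-shaped arrays (bisection runs elementwise).

    Raises
    ------
    ValueError
        If any ``tdp_c > temp_c`` or pressure is not positive.
    RuntimeError
        If the iteration cap is reached before the tolerance (reports the
        offending bracket).
    """
    t = np.asarray(temp_c, dtype=float)
    tdp = np.asarray(tdp_c, dtype=float)
    p_hpa = np.asarray(pressure_kpa, dtype=float) * 10.0
    if np.any(p_hpa <= 0):
        raise ValueError(f"pressure must be > 0 kPa, got {pressure_kpa!r}")
    if np.any(tdp > t + 1e-12):
        raise ValueError(
            f"dewpoint ({tdp_c!r}) must not exceed dry-bulb temperature ({temp_c!r})"
        )

    e_ambient = saturation_vapor_pressure_hpa(tdp)

    def balance(tw):
        # >0 above the root, <0 below: es is increasing and the
        # psychrometric depression term shrinks as tw rises.
        return saturation_vapor_pressure_hpa(tw) - PSYCHROMETER_COEFF * p_hpa * (t - tw) - e_ambient

    lo, hi = np.broadcast_arrays(tdp.copy(), t.copy())
    lo, hi = np.array(lo, dtype=float), np.array(hi, dtype=float)
    for _ in range(WET_BULB_MAX_ITER):
        if np.all(hi - lo <= WET_BULB_TOL_C):
            break
        mid = 0.5 * (lo + hi)
        high_side = balance(mid) > 0.0
        hi = np.where(high_side, mid, hi)
        lo = np.where(high_side, lo, mid)
    else:
        bad = hi - lo > WET_BULB_TOL_C
        raise RuntimeError(
            "wet-bulb bisection did not converge within "
            f"{WET_BULB_MAX_ITER} iterations; open brackets "
            f"[{np.asarray(lo)[bad]!r}, {np.asarray(hi)[bad]!r}]"
        )
    out = 0.5 * (lo + hi)
    if out.ndim == 0:
        return float(out)
    return out


def thi(k, temp_c, rh_pct=None, twet_c=None, tdp_c=None, *, thi5_dialect="printed"):
    """Evaluate THI variant ``k`` (1-9).

    The nine empirical formulas, T dry-bulb degC, Twet wet-bulb degC,
    Tdp dewpoint degC, RH percent (grouping is strict left-to-right):

    ====  ==========================================================
    k     formula
    ====  ==========================================================
    1     0.4*(T + Twet)*1.8 + 32 + 15
    2     (0.15*T + 0.85*Twet)*1.8 + 32
    3     (T*0.35 + Twet*0.65)*1.8 + 32
    4     0.72*(T + Twet) + 40.6
    5     (1.8*T + 32) - (0.55 - 0.0055*RH)*(1.8 + T - 26)
    6     (0.55*T + 0.2*Tdp)*1.8 + 32 + 17.5
    7     T + 0.36*Tdp + 41.2
    8     0.8*T + (RH/100)*(T - 14.4) + 46.4
    9     3.43 + 1.058*T - 0.293*RH + 0.0164*T*RH + 35.7
    ====  ==========================================================

    Variant 5 is published in two readings that differ in their second
    factor; the default ``"printed"`` dialect uses ``(1.8 + T - 26)``,
    while ``thi5_dialect="corrected"`` uses the alternative ``(1.8*T - 26)``.
    Neither is asserted as the true form; at high humidity the multiplier
    ``0.55 - 0.0055*RH`` is near zero and the two are nearly identical.

    Variants 1-4 require ``twet_c``; 6-7 require ``tdp_c``; 5, 8, 9 require
    ``rh_pct``.  Missing required arguments raise ``ValueError``.
    """
    if k not in THI_INDICES:
        raise ValueError(f"THI variant must be 1..9, got {k!r}")
    need = _THI_NEEDS[k]
    t = np.asarray(temp_c, dtype=float)
    if need == "twet":
        if twet_c is None:
            raise ValueError(f"THI{k} requires twet_c")
        tw = np.asarray(twet_c, dtype=float)
    elif need == "tdp":
        if tdp_c is None:
            raise ValueError(f"THI{k} requires tdp_c")
        td = np.asarray(tdp_c, dtype=float)
    else:
        if rh_pct is None:
            raise ValueError(f"THI{k} requires rh_pct")
        rh = np.asarray(rh_pct, dtype=float)

    if k == 1:
        out = 0.4 * (t + tw) * 1.8 + 32 + 15
    elif k == 2:
        out = (0.15 * t + 0.85 * tw) * 1.8 + 32
    elif k == 3:
        out = (t * 0.35 + tw * 0.65) * 1.8 + 32
    elif k == 4:
        out = 0.72 * (t + tw) + 40.6
    elif k == 5:
        if thi5_dialect == "printed":
            second = 1.8 + t - 26
        elif thi5_dialect == "corrected":
            second = 1.8 * t - 26
        else:
            raise ValueError(f"thi5_dialect must be 'printed' or 'corrected', got {thi5_dialect!r}")
        out = (1.8 * t + 32) - (0.55 - 0.0055 * rh) * second
    elif k == 6:
        out = (0.55 * t + 0.2 * td) * 1.8 + 32 + 17.5
    elif k == 7:
        out = t + 0.36 * td + 41.2
    elif k == 8:
        out = 0.8 * t + (rh / 100.0) * (t - 14.4) + 46.4
    else:  # k == 9
        out = 3.43 + 1.058 * t - 0.293 * rh + 0.0164 * t * rh + 35.7
    if np.ndim(out) == 0:
        return float(out)
    return out


def thi_all(temp_c, rh_pct, twet_c, tdp_c, *, thi5_dialect="printed"):
    """All nine THI values as a tuple (scalars) or a 9-column array."""
    vals = [
        thi(k, temp_c, rh_pct=rh_pct, twet_c=twet_c, tdp_c=tdp_c,
            thi5_dialect=thi5_dialect)
        for k in THI_INDICES
    ]
    if np.ndim(vals[0]) == 0:
        return tuple(vals)
    return np.column_stack(vals)


def derive_weather(rec: WeatherRecord, *, thi5_dialect: str = "printed") -> DerivedWeather:
    """Populate dewpoint, wet-bulb and all nine THI values for one record.

    Domain errors from the component calculations are re-raised tagged with
    the record's date.
    """
    try:
        tdp = dewpoint_c(rec.temp_c, rec.rh_pct)
        twet = wet_bulb_c(rec.temp_c, tdp, rec.pressure_kpa)
        vals = thi_all(rec.temp_c, rec.rh_pct, twet, tdp, thi5_dialect=thi5_dialect)
    except (ValueError, RuntimeError) as exc:
        raise type(exc)(f"{rec.date}: {exc}") from exc
    return DerivedWeather(date=rec.date, tdp_c=tdp, twet_c=twet, thi=vals)


#: Column order of the derived columns appended to a daily weather table.
DERIVED_COLUMNS = ["tdp_c", "twet_c"] + [f"thi{k}" for k in THI_INDICES]

WEATHER_COLUMNS = ["date", "temp_c", "rh_pct", "rain_mm", "wind_kmh", "wind_dir_deg"]


def derive_weather_frame(weather: pd.DataFrame, *, thi5_dialect: str = "printed") -> pd.DataFrame:
    """Vectorised :func:`derive_weather` over a daily weather table.

    Expects columns ``date, temp_c, rh_pct`` (the remaining raw columns are
    passed through untouched) and an optional ``pressure_kpa``.  Returns a
    copy with ``tdp_c``, ``twet_c`` and ``thi1`` .. ``thi9`` appended.
    """
    missing = [c for c in ("date", "temp_c", "rh_pct") if c not in weather.columns]
    if missing:
        raise ValueError(f"weather table is missing columns {missing}")
    out = weather.copy()
    t = out["temp_c"].to_numpy(dtype=float)
    rh = out["rh_pct"].to_numpy(dtype=float)
    bad = ~((rh > 0.0) & (rh <= 100.0))
    if bad.any():
        dates = out.loc[bad, "date"].tolist()[:5]
        raise ValueError(f"rh_pct out of (0, 100] on dates {dates}")
    pressure = (
        out["pressure_kpa"].to_numpy(dtype=float)
        if "pressure_kpa" in out.columns
        else STANDARD_PRESSURE_KPA
    )
    tdp = dewpoint_c(t, rh)
    twet = wet_bulb_c(t, tdp, pressure)
    mat = thi_all(t, rh, twet, tdp, thi5_dialect=thi5_dialect)
    out["tdp_c"] = tdp
    out["twet_c"] = twet
    for j, k in enumerate(THI_INDICES):
        out[f"thi{k}"] = mat[:, j]
    return out
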