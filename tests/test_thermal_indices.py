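"""Thermal-index unit tests against independently coded one-line oracles.

The oracle lambdas below are direct transcriptions of the published
formulas, written before and independently of the module; the module must
agree with them to 1e-9.  The wet-bulb solver is checked against a brute
1e-4 degC grid search over the same psychrometer balance.
"""

import datetime

import numpy as np
import pytest

from dairytherm import thermal_indices as ti
from dairytherm.thermal_indices import (
    DerivedWeather,
    WeatherRecord,
    derive_weather,
    derive_weather_frame,
    dewpoint_c,
    thi,
    wet_bulb_c,
)

# ---------------------------------------------------------------- oracles

DEWPOINT_ORACLE = lambda T, RH: 243.5 * (17.67 * T / (243.5 + T) + np.log(RH / 100)) / (
    17.67 - (17.67 * T / (243.5 + T) + np.log(RH / 100))
)

THI_ORACLES = {
    1: lambda T, RH, Twet, Tdp: 0.4 * (T + Twet) * 1.8 + 32 + 15,
    2: lambda T, RH, Twet, Tdp: (0.15 * T + 0.85 * Twet) * 1.8 + 32,
    3: lambda T, RH, Twet, Tdp: (T * 0.35 + Twet * 0.65) * 1.8 + 32,
    4: lambda T, RH, Twet, Tdp: 0.72 * (T + Twet) + 40.6,
    5: lambda T, RH, Twet, Tdp: (1.8 * T + 32) - (0.55 - 0.0055 * RH) * (1.8 + T - 26),
    6: lambda T, RH, Twet, Tdp: (0.55 * T + 0.2 * Tdp) * 1.8 + 32 + 17.5,
    7: lambda T, RH, Twet, Tdp: T + 0.36 * Tdp + 41.2,
    8: lambda T, RH, Twet, Tdp: 0.8 * T + (RH / 100) * (T - 14.4) + 46.4,
    9: lambda T, RH, Twet, Tdp: 3.43 + 1.058 * T - 0.293 * RH + 0.0164 * T * RH + 35.7,
}


def wet_bulb_grid_oracle(T, Tdp, pressure_kpa=101.325, step=1e-4):
    """Brute-force root of the psychrometer balance on a 1e-4 degC grid."""
    es = lambda t: 6.112 * np.exp(17.67 * t / (243.5 + t))
    grid = np.arange(Tdp, T + step, step)
    bal = es(grid) - 6.6e-4 * (pressure_kpa * 10.0) * (T - grid) - es(Tdp)
    return grid[np.argmin(np.abs(bal))]


# ----------------------------------------------------------- dewpoint


class TestDewpoint:
    def test_saturated_air_collapses_to_identity(self):
        assert dewpoint_c(25.0, 100.0) == pytest.approx(25.0, abs=1e-12)

    def test_reference_value_at_half_saturation(self):
        # frozen from the oracle: DEWPOINT_ORACLE(25, 50) = 13.8676170502...
        assert dewpoint_c(25.0, 50.0) == pytest.approx(13.867617050260344, abs=1e-9)

    def test_matches_oracle_on_random_inputs(self, rng):
        T = rng.uniform(-5, 45, 10_000)
        RH = rng.uniform(5, 100, 10_000)
        np.testing.assert_allclose(dewpoint_c(T, RH), DEWPOINT_ORACLE(T, RH), atol=1e-9)

    def test_monotone_in_humidity_and_below_drybulb(self):
        low, mid = dewpoint_c(10.0, 50.0), dewpoint_c(10.0, 80.0)
        assert low < mid < 10.0

    @pytest.mark.parametrize("rh", [0.0, -5.0, 100.5])
    def test_out_of_domain_humidity_raises(self, rh):
        with pytest.raises(ValueError):
            dewpoint_c(20.0, rh)


# ----------------------------------------------------------- wet bulb


class TestWetBulb:
    def test_saturated_bracket_degenerates(self):
        assert wet_bulb_c(20.0, 20.0) == pytest.approx(20.0, abs=1e-3)

    def test_agrees_with_grid_search(self, rng):
        for _ in range(100):
            T = rng.uniform(-5, 45)
            Tdp = dewpoint_c(T, rng.uniform(10, 100))
            P = rng.uniform(80, 105)
            assert wet_bulb_c(T, Tdp, P) == pytest.approx(
                wet_bulb_grid_oracle(T, Tdp, P), abs=0.05
            )

    def test_sits_between_dewpoint_and_drybulb(self):
        tw = wet_bulb_c(25.0, 13.87)
        assert 13.87 < tw < 25.0

    def test_sensitive_to_pressure(self):
        assert wet_bulb_c(25.0, 13.87, 85.0) != pytest.approx(
            wet_bulb_c(25.0, 13.87, 101.325), abs=1e-3
        )

    def test_inverted_bracket_rejected(self):
        with pytest.raises(ValueError):
            wet_bulb_c(15.0, 20.0)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            wet_bulb_c(25.0, 10.0, 0.0)


# ----------------------------------------------------------- THI family


class TestThi:
    def test_reference_value_thi9(self):
        assert thi(9, 30.0, rh_pct=60.0) == pytest.approx(82.81, abs=1e-9)

    def test_reference_value_thi4_saturated(self):
        assert thi(4, 25.0, twet_c=25.0) == pytest.approx(76.6, abs=1e-9)

    @pytest.mark.parametrize("k", sorted(THI_ORACLES))
    def test_matches_one_line_oracle(self, k, rng):
        T = rng.uniform(-5, 45, 10_000)
        RH = rng.uniform(5, 100, 10_000)
        Tdp = dewpoint_c(T, RH)
        Twet = wet_bulb_c(T, Tdp)
        got = thi(k, T, rh_pct=RH, twet_c=Twet, tdp_c=Tdp)
        np.testing.assert_allclose(got, THI_ORACLES[k](T, RH, Twet, Tdp), atol=1e-9)

    def test_thi1_minus_thi4_is_identically_6_4(self, rng):
        # algebraic identity: 0.4*1.8 = 0.72 so the variants differ only in
        # the constant, 47 - 40.6 (matches the printed yearly means, e.g.
        # 70.6 - 64.2)
        T = rng.uniform(-5, 45, 1000)
        Twet = T - rng.uniform(0, 10, 1000)
        diff = thi(1, T, twet_c=Twet) - thi(4, T, twet_c=Twet)
        np.testing.assert_allclose(diff, 6.4, atol=1e-9)

    @pytest.mark.parametrize("k", range(1, 10))
    def test_strictly_increasing_in_temperature(self, k):
        T = np.linspace(0, 45, 200)
        RH = np.full_like(T, 60.0)
        Tdp = dewpoint_c(T, RH)
        Twet = wet_bulb_c(T, Tdp)
        vals = thi(k, T, rh_pct=RH, twet_c=Twet, tdp_c=Tdp)
        assert np.all(np.diff(vals) > 0)

    def test_thi5_dialects_differ_except_near_critical_humidity(self):
        printed = thi(5, 30.0, rh_pct=50.0)
        corrected = thi(5, 30.0, rh_pct=50.0, thi5_dialect="corrected")
        assert printed != pytest.approx(corrected, abs=1e-6)
        # at RH = 100 the multiplier is exactly zero in both dialects
        assert thi(5, 30.0, rh_pct=100.0) == pytest.approx(
            thi(5, 30.0, rh_pct=100.0, thi5_dialect="corrected"), abs=1e-12
        )

    def test_unknown_variant_and_missing_arguments_raise(self):
        with pytest.raises(ValueError):
            thi(10, 25.0, rh_pct=50.0)
        with pytest.raises(ValueError):
            thi(1, 25.0, rh_pct=50.0)  # needs twet_c
        with pytest.raises(ValueError):
            thi(6, 25.0, rh_pct=50.0)  # needs tdp_c


# ------------------------------------------------- records and batch derive


class TestDeriveWeather:
    def test_saturated_record_collapses(self):
        rec = WeatherRecord(date=datetime.date(2018, 1, 1), temp_c=22.0, rh_pct=100.0)
        der = derive_weather(rec)
        assert der.tdp_c == pytest.approx(22.0, abs=1e-3)
        assert der.twet_c == pytest.approx(22.0, abs=1e-3)
        assert len(der.thi) == 9

    def test_psychrometric_ordering_on_random_sweep(self, rng):
        T = rng.uniform(-5, 45, 10_000)
        RH = rng.uniform(5, 100, 10_000)
        Tdp = dewpoint_c(T, RH)
        Twet = wet_bulb_c(T, Tdp)
        assert np.all(Tdp <= Twet + 1e-3)
        assert np.all(Twet <= T + 1e-3)
        sat = np.isclose(RH, 100.0, atol=1e-9)
        assert np.all(np.abs(Tdp[sat] - T[sat]) < 1e-3)

    def test_invalid_record_rejected_with_field_and_date(self):
        with pytest.raises(ValueError, match="rh_pct"):
            WeatherRecord(date=datetime.date(2018, 2, 2), temp_c=20.0, rh_pct=0.0)

    def test_batch_derivation_holds_invariants(self, small_weather):
        der = derive_weather_frame(small_weather)
        assert len(der) == len(small_weather)
        assert (der.tdp_c <= der.twet_c + 1e-3).all()
        assert (der.twet_c <= der.temp_c + 1e-3).all()
        for k in range(1, 10):
            assert f"thi{k}" in der.columns

    def test_batch_derivation_flags_bad_humidity_with_date(self, small_weather):
        bad = small_weather.copy()
        bad.loc[3, "rh_pct"] = 0.0
        with pytest.raises(ValueError, match="rh_pct"):
            derive_weather_frame(bad)

    def test_idempotent_on_same_record(self):
        rec = WeatherRecord(date=datetime.date(2019, 3, 3), temp_c=31.0, rh_pct=40.0)
        assert derive_weather(rec) == derive_weather(rec)
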