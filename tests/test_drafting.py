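"""Drafting-gate tests: routing rules, state machine, threshold monotonicity."""

import numpy as np
import pandas as pd
import pytest

import dairytherm as dt
from dairytherm.dataset import INPUT_COLUMNS
from dairytherm.drafting import (
    CowStressState,
    Route,
    StressState,
    Thresholds,
    assess_cow,
    audit_decision_log,
    run_drafting_sim,
)


@pytest.fixture(scope="module")
def one_cow_inputs(request):
    small_features = request.getfixturevalue("small_features")
    return small_features.inputs.iloc[[0]].copy()


def _always_short_thresholds(**kw):
    # minima far above any plausible prediction: shortfall always fires, so
    # the stress flag reduces to the THI condition
    kw.setdefault("min_milk_yield_kg", 1e6)
    kw.setdefault("min_protein_pct", 1e6)
    kw.setdefault("min_fat_pct", 1e6)
    return Thresholds(**kw)


class TestThresholds:
    def test_thi_threshold_plausibility_window(self):
        with pytest.raises(ValueError):
            Thresholds(thi_stress=40.0)
        with pytest.raises(ValueError):
            Thresholds(thi_stress=95.0)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            Thresholds(mode="xor")


class TestAssessCow:
    def test_cool_day_routes_to_milking(self, trained_model, one_cow_inputs):
        model, _ = trained_model
        decision, state = assess_cow(
            one_cow_inputs, thi9=55.0, model=model,
            thresholds=_always_short_thresholds(),
            state=CowStressState(cow_id="c1"),
        )
        assert decision.route == Route.MILKING
        assert state.state == StressState.NORMAL

    def test_hot_day_with_shortfall_routes_to_cooling(self, trained_model, one_cow_inputs):
        model, _ = trained_model
        decision, state = assess_cow(
            one_cow_inputs, thi9=80.0, model=model,
            thresholds=_always_short_thresholds(),
            state=CowStressState(cow_id="c1"),
        )
        assert decision.route == Route.COOLING
        assert state.state == StressState.STRESSED_DAY1
        assert "thi9" in decision.trigger

    def test_persistent_stress_gets_cooled_and_milked(self, trained_model, one_cow_inputs):
        model, _ = trained_model
        thresholds = _always_short_thresholds()
        state = CowStressState(cow_id="c1")
        _, state = assess_cow(one_cow_inputs, 80.0, model, thresholds, state)
        decision, state = assess_cow(one_cow_inputs, 81.0, model, thresholds, state)
        assert decision.route == Route.COOLING_AND_MILK
        assert state.state == StressState.STRESSED_PERSISTENT
        # a third hot day keeps her in the persistent state
        decision, state = assess_cow(one_cow_inputs, 82.0, model, thresholds, state)
        assert decision.route == Route.COOLING_AND_MILK
        # recovery resets to NORMAL
        decision, state = assess_cow(one_cow_inputs, 50.0, model, thresholds, state)
        assert decision.route == Route.MILKING
        assert state.state == StressState.NORMAL

    def test_hot_day_without_shortfall_needs_no_cooling_in_and_mode(
        self, trained_model, one_cow_inputs
    ):
        model, _ = trained_model
        lenient = Thresholds(
            min_milk_yield_kg=-1e6, min_protein_pct=-1e6, min_fat_pct=-1e6
        )
        decision, _ = assess_cow(
            one_cow_inputs, 85.0, model, lenient, CowStressState(cow_id="c1")
        )
        assert decision.route == Route.MILKING

    def test_any_mode_flags_on_heat_alone(self, trained_model, one_cow_inputs):
        model, _ = trained_model
        lenient_any = Thresholds(
            min_milk_yield_kg=-1e6, min_protein_pct=-1e6, min_fat_pct=-1e6, mode="any"
        )
        decision, _ = assess_cow(
            one_cow_inputs, 85.0, model, lenient_any, CowStressState(cow_id="c1")
        )
        assert decision.route == Route.COOLING


def _sim_inputs(derived, cow_days):
    merged = cow_days.merge(
        derived[["date"] + [c for c in INPUT_COLUMNS if c in derived.columns]],
        on="date", how="left",
    )
    return merged


class TestRunDraftingSim:
    def test_all_cool_horizon_means_all_milking(self, small_derived, small_cow_days, trained_model):
        model, _ = trained_model
        cool_dates = small_derived[small_derived.thi9 < 65]["date"]
        days = small_cow_days[small_cow_days.date.isin(cool_dates)]
        log = run_drafting_sim(
            _sim_inputs(small_derived, days), small_derived, model,
            _always_short_thresholds(thi_stress=72.0),
        )
        assert (log["route"] == "MILKING").all()

    def test_summer_herd_log_is_exhaustive_and_legal(self, small_derived, small_cow_days, trained_model):
        model, _ = trained_model
        months = pd.to_datetime(small_derived["date"]).dt.month
        summer_dates = small_derived.loc[months.isin([12, 1, 2]), "date"]
        days = small_cow_days[small_cow_days.date.isin(summer_dates)]
        log = run_drafting_sim(
            _sim_inputs(small_derived, days), small_derived, model,
            _always_short_thresholds(),
        )
        assert len(log) == len(days)  # one decision per cow-day
        audit_decision_log(log)  # raises on any illegal transition

    def test_cooling_precedes_cooling_and_milk(self, small_derived, small_cow_days, trained_model):
        model, _ = trained_model
        log = run_drafting_sim(
            _sim_inputs(small_derived, small_cow_days), small_derived, model,
            _always_short_thresholds(),
        )
        for _, group in log.groupby("cow_id"):
            g = group.sort_values("date").reset_index(drop=True)
            both = g[g.route == "COOLING_AND_MILK"]
            if len(both):
                first_cool = g[g.route == "COOLING"].index.min()
                assert first_cool < both.index.min()

    def test_raising_thi_threshold_never_increases_cooling(
        self, small_derived, small_cow_days, trained_model
    ):
        model, _ = trained_model
        inputs = _sim_inputs(small_derived, small_cow_days)
        counts = []
        for thr in (65.0, 72.0, 79.0, 86.0):
            log = run_drafting_sim(
                inputs, small_derived, model, _always_short_thresholds(thi_stress=thr)
            )
            counts.append((log["route"] != "MILKING").sum())
        assert counts == sorted(counts, reverse=True)

    def test_always_milk_flag_removes_unmilked_cooling_days(
        self, small_derived, small_cow_days, trained_model
    ):
        model, _ = trained_model
        inputs = _sim_inputs(small_derived, small_cow_days)
        log = run_drafting_sim(
            inputs, small_derived, model, _always_short_thresholds(), always_milk=True
        )
        assert (log["route"] != "COOLING").all()

    def test_weather_gap_rejected(self, small_derived, small_cow_days, trained_model):
        model, _ = trained_model
        inputs = _sim_inputs(small_derived, small_cow_days)
        with pytest.raises(ValueError, match="gap"):
            run_drafting_sim(inputs, small_derived.iloc[:-100], model, Thresholds())

    def test_audit_catches_forged_transition(self, small_derived, small_cow_days, trained_model):
        model, _ = trained_model
        log = run_drafting_sim(
            _sim_inputs(small_derived, small_cow_days), small_derived, model,
            _always_short_thresholds(),
        )
        forged = log.copy()
        # forge a NORMAL -> STRESSED_PERSISTENT jump on some cow's first day
        first_idx = forged.groupby("cow_id").head(1).index[0]
        forged.loc[first_idx, ["state", "route"]] = ["STRESSED_PERSISTENT", "COOLING_AND_MILK"]
        with pytest.raises(AssertionError):
            audit_decision_log(forged)
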