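"""Automated drafting-gate decision system for heat-stress management.

Each day, every cow presenting at the gate is assessed from the day's
weather and her management record: the trained network predicts her four
production targets, and she is flagged heat-stressed when the environment
is hot (THI9 above a threshold) AND any predicted output falls below the
farm's minimum for volume or milk quality.  Flagged cows are drafted to a
sprinkler cooling area; a cow still flagged on the following day is cooled
AND milked (to avoid mastitis).  Unflagged cows go to normal milking and
their stress state resets.

States:  NORMAL -> STRESSED_DAY1 -> {STRESSED_PERSISTENT, NORMAL};
STRESSED_PERSISTENT -> {STRESSED_PERSISTENT, NORMAL}.  Routes: COOLING
(first stressed day), COOLING_AND_MILK (persistently stressed), MILKING.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
from typing import Sequence

import numpy as np
import pandas as pd

from .brann import TrainedModel
from .dataset import INPUT_COLUMNS, TARGET_COLUMNS

__all__ = [
    "Thresholds",
    "StressState",
    "CowStressState",
    "Route",
    "DraftingDecision",
    "assess_cow",
    "run_drafting_sim",
    "audit_decision_log",
]


class StressState(str, enum.Enum):
    NORMAL = "NORMAL"
    STRESSED_DAY1 = "STRESSED_DAY1"
    STRESSED_PERSISTENT = "STRESSED_PERSISTENT"


class Route(str, enum.Enum):
    MILKING = "MILKING"
    COOLING = "COOLING"
    COOLING_AND_MILK = "COOLING_AND_MILK"


#: Legal state transitions (previous -> allowed next states).
LEGAL_TRANSITIONS = {
    StressState.NORMAL: {StressState.NORMAL, StressState.STRESSED_DAY1},
    StressState.STRESSED_DAY1: {StressState.NORMAL, StressState.STRESSED_PERSISTENT},
    StressState.STRESSED_PERSISTENT: {StressState.NORMAL, StressState.STRESSED_PERSISTENT},
}


@dataclasses.dataclass
class Thresholds:
    """Farm-set minima for volume and milk quality, plus the THI9 trigger.

    A cow is heat-stressed when THI9 exceeds ``thi_stress`` and (by
    default) at least one predicted output is below its minimum;
    ``mode="any"`` makes either condition alone sufficient.
    """

    min_milk_yield_kg: float = 20.0
    min_protein_pct: float = 3.0
    min_fat_pct: float = 3.5
    thi_stress: float = 72.0
    mode: str = "and"

    def __post_init__(self) -> None:
        for f in ("min_milk_yield_kg", "min_protein_pct", "min_fat_pct", "thi_stress"):
            if not np.isfinite(getattr(self, f)):
                raise ValueError(f"{f} must be finite")
        if not 50.0 <= self.thi_stress <= 90.0:
            raise ValueError(
                f"thi_stress must be in [50, 90], got {self.thi_stress!r}"
            )
        if self.mode not in ("and", "any"):
            raise ValueError(f"mode must be 'and' or 'any', got {self.mode!r}")


@dataclasses.dataclass
class CowStressState:
    """Per-cow rolling stress assessment."""

    cow_id: str
    state: StressState = StressState.NORMAL
    last_assessed: _dt.date | None = None


@dataclasses.dataclass(frozen=True)
class DraftingDecision:
    """One gate decision: where the cow was routed and why."""

    cow_id: str
    date: _dt.date
    route: Route
    trigger: tuple[str, ...]
    predicted: dict[str, float]


def _shortfalls(pred_row: pd.Series, thresholds: Thresholds) -> list[str]:
    out = []
    if pred_row["milk_yield_kg"] < thresholds.min_milk_yield_kg:
        out.append("milk_yield")
    if pred_row["protein_pct"] < thresholds.min_protein_pct:
        out.append("protein")
    if pred_row["fat_pct"] < thresholds.min_fat_pct:
        out.append("fat")
    return out


def assess_cow(
    inputs: pd.DataFrame,
    thi9: float,
    model: TrainedModel,
    thresholds: Thresholds,
    state: CowStressState,
) -> tuple[DraftingDecision, CowStressState]:
    """Assess one cow-day and route her through the gate.

    ``inputs`` is a single-row table with the 21 frozen input columns for
    this cow and day (original units).  Returns the decision and the cow's
    updated stress state; illegal transitions cannot occur by construction.
    """
    if len(inputs) != 1:
        raise ValueError("assess_cow expects exactly one cow-day row")
    pred = model.predict(inputs).iloc[0]
    short = _shortfalls(pred, thresholds)
    hot = thi9 > thresholds.thi_stress
    if thresholds.mode == "and":
        flagged = hot and bool(short)
    else:
        flagged = hot or bool(short)

    trigger: list[str] = []
    if flagged:
        if hot:
            trigger.append("thi9")
        trigger.extend(short)

    if not flagged:
        new_state = StressState.NORMAL
        route = Route.MILKING
    elif state.state == StressState.NORMAL:
        new_state = StressState.STRESSED_DAY1
        route = Route.COOLING
    else:  # STRESSED_DAY1 or STRESSED_PERSISTENT, flagged again
        new_state = StressState.STRESSED_PERSISTENT
        route = Route.COOLING_AND_MILK

    date = inputs.index[0] if isinstance(inputs.index[0], _dt.date) else None
    decision = DraftingDecision(
        cow_id=state.cow_id,
        date=date,
        route=route,
        trigger=tuple(trigger),
        predicted={k: float(pred[k]) for k in TARGET_COLUMNS},
    )
    return decision, CowStressState(cow_id=state.cow_id, state=new_state, last_assessed=date)


def run_drafting_sim(
    cow_day_inputs: pd.DataFrame,
    derived_weather: pd.DataFrame,
    model: TrainedModel,
    thresholds: Thresholds | None = None,
    *,
    always_milk: bool = False,
) -> pd.DataFrame:
    """Replay the drafting gate over a horizon of cow-days.

    ``cow_day_inputs`` carries ``cow_id``, ``date`` and the 21 input
    columns; ``derived_weather`` must cover every date (gaps raise).
    Decisions are made in chronological order per cow.  With
    ``always_milk`` every COOLING route is upgraded to COOLING_AND_MILK
    (for farms that milk regardless of first-day stress).

    Returns the decision log: one row per cow-day with route, trigger and
    the four predictions, plus the post-decision stress state.
    """
    thresholds = thresholds or Thresholds()
    weather = derived_weather.copy()
    weather["date"] = pd.to_datetime(weather["date"]).dt.date
    days = cow_day_inputs.copy()
    days["date"] = pd.to_datetime(days["date"]).dt.date

    gaps = sorted(set(days["date"]) - set(weather["date"]))
    if gaps:
        raise ValueError(f"weather coverage gap on {len(gaps)} dates, first few: {gaps[:5]}")
    thi9_by_date = dict(zip(weather["date"], weather["thi9"]))

    days = days.sort_values(["date", "cow_id"], kind="mergesort").reset_index(drop=True)

    # Batch-predict all cow-days at once; routing itself stays sequential.
    preds = model.predict(days[INPUT_COLUMNS])

    states: dict[str, StressState] = {}
    records = []
    for i in range(len(days)):
        row = days.iloc[i]
        pred = preds.iloc[i]
        cow = row["cow_id"]
        thi9 = float(thi9_by_date[row["date"]])
        short = _shortfalls(pred, thresholds)
        hot = thi9 > thresholds.thi_stress
        flagged = (hot and bool(short)) if thresholds.mode == "and" else (hot or bool(short))

        prev = states.get(cow, StressState.NORMAL)
        if not flagged:
            new_state, route = StressState.NORMAL, Route.MILKING
        elif prev == StressState.NORMAL:
            new_state, route = StressState.STRESSED_DAY1, Route.COOLING
        else:
            new_state, route = StressState.STRESSED_PERSISTENT, Route.COOLING_AND_MILK
        if always_milk and route == Route.COOLING:
            route = Route.COOLING_AND_MILK

        trigger = []
        if flagged:
            if hot:
                trigger.append("thi9")
            trigger.extend(short)

        states[cow] = new_state
        records.append(
            {
                "cow_id": cow,
                "date": row["date"],
                "route": route.value,
                "state": new_state.value,
                "trigger": "+".join(trigger),
                "pred_milk_yield_kg": float(pred["milk_yield_kg"]),
                "pred_protein_pct": float(pred["protein_pct"]),
                "pred_fat_pct": float(pred["fat_pct"]),
                "pred_feed_intake_kg": float(pred["feed_intake_kg"]),
            }
        )
    return pd.DataFrame(records)


def audit_decision_log(log: pd.DataFrame) -> None:
    """Replay a decision log against the transition table; raise on any
    illegal state transition or route/state mismatch."""
    for cow, group in log.sort_values("date", kind="mergesort").groupby("cow_id"):
        prev = StressState.NORMAL
        for _, row in group.iterrows():
            cur = StressState(row["state"])
            if cur not in LEGAL_TRANSITIONS[prev]:
                raise AssertionError(
                    f"illegal transition {prev.value} -> {cur.value} "
                    f"for {cow} on {row['date']}"
                )
            route = Route(row["route"])
            if cur == StressState.NORMAL and route != Route.MILKING:
                raise AssertionError(f"NORMAL state must route MILKING ({cow}, {row['date']})")
            if cur == StressState.STRESSED_PERSISTENT and route != Route.COOLING_AND_MILK:
                raise AssertionError(
                    f"PERSISTENT state must route COOLING_AND_MILK ({cow}, {row['date']})"
                )
            prev = cur
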