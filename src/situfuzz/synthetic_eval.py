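"""Synthetic daily-routine traces, accuracy scoring and confirmation logs.

No public dataset of labelled smartphone context traces exists for this
kind of engine, so end-to-end evaluation runs on synthetic agents: a
:class:`RoutineScenario` names a handful of places and a schedule of
episodes (time window, place, activity mixture, intended situation
label), and :func:`simulate_routine` emits one raw observation per
minute with isotropic Gaussian GPS noise, noisy activity probabilities
and a linearly discharging battery.  Ground truth is the episode label,
which lets :func:`evaluate_accuracy` score the engine the same way a
field study scores user confirmations: a tick counts as correct when
the label is among the maximally activated situations, incorrect when
some situation fired but the label is not among them.  Ticks where
nothing fires are excluded from the headline percentage — in the field
only an *identified* situation can be confirmed — and tracked
separately as misses or correct negatives.

:func:`analyze_confirmations` implements the confirmation-log
arithmetic itself (per-participant and pooled percentage of "yes"
answers), and :func:`example_confirmation_counts` bundles the
confirmation counts of a 12-participant, 7-day field study of this
engine design (490 confirmations, 451 correct) as a worked dataset.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .context_provider import RawObservation, preprocess, write_trace_csv
from .fuzzy_core import ACTIVITY_CLASSES
from .rule_engine import GeoPoint, SituationRule, current_situation

__all__ = [
    "Episode",
    "RoutineScenario",
    "simulate_routine",
    "weekday_routine_scenario",
    "routine_rules",
    "evaluate_accuracy",
    "AccuracySummary",
    "analyze_confirmations",
    "example_confirmation_counts",
    "truncate_percent",
]

_M_PER_DEG_LAT = 111_320.0


class Episode(BaseModel):
    """One scheduled block of an agent's day."""

    start: datetime
    end: datetime
    place: str
    label: Optional[str] = None
    activities: dict[str, float]

    @field_validator("activities")
    @classmethod
    def _acts(cls, v):
        unknown = set(v) - set(ACTIVITY_CLASSES)
        if unknown:
            raise ValueError(f"unknown activity classes {sorted(unknown)}")
        if any(not 0.0 <= w <= 1.0 for w in v.values()):
            raise ValueError("activity mixture weights must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _ordered(self):
        if self.end <= self.start:
            raise ValueError("episode end must be after its start")
        return self


class RoutineScenario(BaseModel):
    """Places, episode schedule and noise levels of a synthetic agent.

    Defaults model a realistic smartphone: 10 m GPS noise (a typical
    open-sky fix), mild activity-probability noise, and a 4 %/h battery
    discharge — enough to walk the scheduler through its battery tiers
    over a day.
    """

    places: dict[str, tuple[float, float]]  # name -> (lat, lon)
    episodes: list[Episode]
    gps_sigma_m: float = Field(default=10.0, ge=0.0)
    activity_noise: float = Field(default=0.05, ge=0.0, le=1.0)
    #: activity mixture used between episodes (commuting by vehicle).
    gap_activities: dict[str, float] = Field(default_factory=lambda: {"in_vehicle": 0.9})
    battery_start: float = Field(default=0.95, ge=0.0, le=1.0)
    battery_discharge_per_hour: float = Field(default=0.04, ge=0.0)

    @model_validator(mode="after")
    def _check(self):
        eps = self.episodes
        if not eps:
            raise ValueError("scenario needs at least one episode")
        for e in eps:
            if e.place not in self.places:
                raise ValueError(f"episode references unknown place {e.place!r}")
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"episodes overlap: {a.label or a.place} ends {a.end}, "
                    f"{b.label or b.place} starts {b.start}"
                )
        return self

    def to_json_dict(self) -> dict:
        import json

        return json.loads(self.model_dump_json())

    @classmethod
    def from_file(cls, path: str | Path) -> "RoutineScenario":
        import json

        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.model_validate(data)


def _noisy_position(
    rng: np.random.Generator, lat: float, lon: float, sigma_m: float
) -> tuple[float, float]:
    north, east = rng.normal(0.0, sigma_m, size=2) if sigma_m > 0 else (0.0, 0.0)
    dlat = north / _M_PER_DEG_LAT
    dlon = east / (_M_PER_DEG_LAT * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def _noisy_activity(
    rng: np.random.Generator, mixture: dict[str, float], noise: float
) -> dict[str, float]:
    probs = {}
    for c in ACTIVITY_CLASSES:
        base = mixture.get(c, 0.0)
        if noise > 0:
            base = base + rng.normal(0.0, noise)
        probs[c] = float(np.clip(base, 0.0, 1.0))
    # "on foot" generalizes walking and running
    if "on_foot" not in mixture:
        probs["on_foot"] = min(1.0, probs["walking"] + probs["running"])
    return {c: 100.0 * p for c, p in probs.items()}


def simulate_routine(
    scenario: RoutineScenario, seed: int
) -> tuple[list[RawObservation], list[Optional[str]]]:
    """One observation per minute with the scenario's ground-truth labels.

    Between episodes the agent stays at the previous episode's place
    with the scenario's gap activity mixture and no label.  Labels
    depend only on the schedule, so two seeds yield different traces
    with identical label sequences; one seed yields byte-identical
    traces.
    """
    rng = np.random.default_rng(seed)
    eps = scenario.episodes
    t = eps[0].start
    end = eps[-1].end
    observations: list[RawObservation] = []
    labels: list[Optional[str]] = []
    ep_idx = 0
    current_place = eps[0].place
    while t < end:
        while ep_idx < len(eps) and t >= eps[ep_idx].end:
            current_place = eps[ep_idx].place
            ep_idx += 1
        in_episode = ep_idx < len(eps) and eps[ep_idx].start <= t < eps[ep_idx].end
        if in_episode:
            ep = eps[ep_idx]
            place, mixture, label = ep.place, ep.activities, ep.label
        else:
            place, mixture, label = current_place, scenario.gap_activities, None
        lat0, lon0 = scenario.places[place]
        lat, lon = _noisy_position(rng, lat0, lon0, scenario.gps_sigma_m)
        hours = (t - eps[0].start).total_seconds() / 3600.0
        battery = float(
            np.clip(scenario.battery_start - scenario.battery_discharge_per_hour * hours, 0.01, 1.0)
        )
        observations.append(
            RawObservation(
                timestamp=t,
                latitude=lat,
                longitude=lon,
                altitude=None,
                activity=_noisy_activity(rng, mixture, scenario.activity_noise),
                battery=battery,
                location_fix_time=t,
            )
        )
        labels.append(label)
        t += timedelta(minutes=1)
    return observations, labels


# ---------------------------------------------------------------------------
# A reference weekday routine
# ---------------------------------------------------------------------------

def weekday_routine_scenario(
    gps_sigma_m: float = 10.0, activity_noise: float = 0.05
) -> RoutineScenario:
    """A plausible working-day routine with well-separated anchors.

    Home, workplace (2.2 km east) and gym (2.5 km south): every pair of
    anchors is at least 2 km apart, so the geofence terms of different
    situations do not overlap at realistic GPS noise.  The day is a
    Wednesday: wake-up at home, office hours at work, a training block
    at the gym and an evening at home, with unlabelled vehicle commutes
    in between.
    """
    day = "2017-01-11"  # a Wednesday
    home = (41.1500, -8.6100)
    work = (41.1500, -8.6100 + 2200.0 / (_M_PER_DEG_LAT * math.cos(math.radians(41.15))))
    gym = (41.1500 - 2500.0 / _M_PER_DEG_LAT, -8.6100)

    def ep(t0, t1, place, label, activities):
        return Episode(
            start=f"{day}T{t0}", end=f"{day}T{t1}", place=place, label=label, activities=activities
        )

    return RoutineScenario(
        places={"home": home, "work": work, "gym": gym},
        episodes=[
            ep("06:30", "07:45", "home", "morning_routine", {"still": 1.0}),
            ep("09:00", "17:00", "work", "working", {"still": 0.6, "walking": 0.4}),
            ep("17:30", "18:45", "gym", "exercising", {"walking": 0.5, "running": 0.5}),
            ep("19:30", "23:00", "home", "relaxing_home", {"still": 0.9, "tilting": 0.1}),
        ],
        gps_sigma_m=gps_sigma_m,
        activity_noise=activity_noise,
    )


def routine_rules() -> list[SituationRule]:
    """Situation rules matching :func:`weekday_routine_scenario`."""
    scenario = weekday_routine_scenario()
    p = {name: GeoPoint(lat=lat, lon=lon) for name, (lat, lon) in scenario.places.items()}
    mk = SituationRule
    return [
        mk(
            id="morning_routine",
            name="morning routine",
            anchor=p["home"],
            location_term="same_place",
            day_terms=frozenset({"weekday"}),
            time_terms=frozenset({"morning"}),
            activities=frozenset({"still"}),
        ),
        mk(
            id="working",
            name="working",
            anchor=p["work"],
            location_term="same_place",
            day_terms=frozenset({"weekday"}),
            time_terms=frozenset({"morning", "afternoon"}),
            activities=frozenset({"still", "walking"}),
        ),
        mk(
            id="exercising",
            name="physical activity",
            anchor=p["gym"],
            location_term="same_place",
            day_terms=frozenset({"weekday"}),
            time_terms=frozenset({"afternoon", "night"}),
            activities=frozenset({"walking", "running"}),
        ),
        mk(
            id="relaxing_home",
            name="relaxing at home",
            anchor=p["home"],
            location_term="same_place",
            day_terms=frozenset({"weekday"}),
            time_terms=frozenset({"night"}),
            activities=frozenset({"still", "tilting"}),
        ),
    ]


# ---------------------------------------------------------------------------
# Accuracy scoring
# ---------------------------------------------------------------------------

class AccuracySummary(dict):
    """Confusion summary; a plain dict with a convenience ``percent``."""

    @property
    def percent(self) -> float:
        return self["overall"]["percent"]


def evaluate_accuracy(
    observations: Sequence[RawObservation],
    labels: Sequence[Optional[str]],
    rules: Iterable[SituationRule],
) -> AccuracySummary:
    """Score the engine tick by tick against ground-truth labels.

    A tick is *correct* when its label is among the maximally activated
    situation ids, *incorrect* when some situation fired but the label
    is not among them (including fires on unlabelled ticks).  Labelled
    ticks where nothing fired are *missed*; unlabelled quiet ticks are
    *correct negatives*.  The headline percentage covers only fired
    ticks, mirroring a confirmation protocol where only an identified
    situation can be judged.
    """
    observations = list(observations)
    labels = list(labels)
    if not observations:
        raise ValueError("empty trace")
    if len(observations) != len(labels):
        raise ValueError(f"{len(observations)} observations but {len(labels)} labels")
    rules = list(rules)
    per: dict[str, dict[str, int]] = {}
    correct = incorrect = missed = correct_negative = 0
    for obs, label in zip(observations, labels):
        snap = preprocess(obs)
        ids = current_situation(rules, snap)
        key = label if label is not None else "(none)"
        row = per.setdefault(key, {"correct": 0, "incorrect": 0, "missed": 0})
        if ids:
            if label is not None and label in ids:
                correct += 1
                row["correct"] += 1
            else:
                incorrect += 1
                row["incorrect"] += 1
        elif label is None:
            correct_negative += 1
        else:
            missed += 1
            row["missed"] += 1
    confirmed = correct + incorrect
    percent = 100.0 * correct / confirmed if confirmed else float("nan")
    return AccuracySummary(
        overall={
            "correct": correct,
            "incorrect": incorrect,
            "missed": missed,
            "correct_negative": correct_negative,
            "confirmed": confirmed,
            "percent": percent,
        },
        per_situation=per,
    )


# ---------------------------------------------------------------------------
# Confirmation-log arithmetic
# ---------------------------------------------------------------------------

def truncate_percent(p: float) -> float:
    """Display convention for percentages: truncate to 2 decimals."""
    return math.floor(p * 100.0) / 100.0


def _counts_from_records(records: pd.DataFrame) -> pd.DataFrame:
    answers = records["answer"].astype(str).str.lower()
    if not set(answers) <= {"yes", "no"}:
        bad = sorted(set(answers) - {"yes", "no"})
        raise ValueError(f"answers must be yes/no, got {bad}")
    grouped = records.assign(_yes=(answers == "yes")).groupby("participant")["_yes"]
    return pd.DataFrame(
        {"correct": grouped.sum().astype(int), "incorrect": (grouped.count() - grouped.sum()).astype(int)}
    ).reset_index()


def analyze_confirmations(data: pd.DataFrame) -> dict:
    """Per-participant and pooled success percentages from confirmations.

    ``data`` is either a raw confirmation log (columns ``participant``,
    ``answer`` with yes/no, plus whatever else was logged) or a counts
    table (columns ``participant``, ``correct``, ``incorrect``).  The
    pooled percentage is computed over summed counts, not averaged over
    participants.  Percentages carry a ``percent_display`` truncated to
    two decimals, the convention used when showing them to users.
    """
    if {"correct", "incorrect"} <= set(data.columns):
        counts = data[["participant", "correct", "incorrect"]].copy()
    elif {"participant", "answer"} <= set(data.columns):
        counts = _counts_from_records(data)
    else:
        raise ValueError(
            "expected columns participant/correct/incorrect or participant/answer"
        )
    counts["correct"] = counts["correct"].astype(int)
    counts["incorrect"] = counts["incorrect"].astype(int)
    total = counts["correct"] + counts["incorrect"]
    if (total == 0).any():
        bad = counts.loc[total == 0, "participant"].tolist()
        raise ValueError(f"participants with zero confirmations: {bad}")
    per = []
    for _, row in counts.iterrows():
        n = row["correct"] + row["incorrect"]
        pct = 100.0 * row["correct"] / n
        per.append(
            {
                "participant": row["participant"],
                "correct": int(row["correct"]),
                "incorrect": int(row["incorrect"]),
                "confirmations": int(n),
                "percent": pct,
                "percent_display": truncate_percent(pct),
            }
        )
    tot_c = int(counts["correct"].sum())
    tot_i = int(counts["incorrect"].sum())
    overall_pct = 100.0 * tot_c / (tot_c + tot_i)
    return {
        "per_participant": per,
        "overall": {
            "correct": tot_c,
            "incorrect": tot_i,
            "confirmations": tot_c + tot_i,
            "percent": overall_pct,
            "percent_display": truncate_percent(overall_pct),
        },
    }


def example_confirmation_counts() -> pd.DataFrame:
    """Confirmation counts from a 12-participant, 7-day field study.

    Each participant defined two to six situations and answered yes/no
    prompts whenever a new situation was identified; 490 confirmations
    were collected, 451 of them "yes".  Bundled as a worked dataset for
    :func:`analyze_confirmations`.
    """
    rows = [
        (1, 3, 45, 0),
        (2, 3, 28, 3),
        (3, 4, 42, 0),
        (4, 5, 33, 5),
        (5, 3, 38, 4),
        (6, 6, 54, 0),
        (7, 5, 60, 9),
        (8, 5, 73, 11),
        (9, 4, 14, 4),
        (10, 4, 10, 1),
        (11, 3, 43, 1),
        (12, 6, 11, 1),
    ]
    return pd.DataFrame(rows, columns=["participant", "defined", "correct", "incorrect"])


def simulate_to_files(
    scenario: RoutineScenario,
    seed: int,
    trace_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write a simulated trace as CSV (and its labels alongside)."""
    observations, labels = simulate_routine(scenario, seed)
    write_trace_csv(observations, trace_path)
    if labels_path is not None:
        pd.DataFrame(
            {
                "timestamp": [o.timestamp.isoformat() for o in observations],
                "label": ["" if l is None else l for l in labels],
            }
        ).to_csv(labels_path, index=False)
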