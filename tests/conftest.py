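"""Shared fixtures: snapshot builders and a small reference rule set."""

from __future__ import annotations

from datetime import datetime

import pytest

from situfuzz import (
    ContextSnapshot,
    GeoPoint,
    SituationRule,
    day_week_value,
    time_of_day_value,
)

ANCHOR = (41.1500, -8.6100)


_DEFAULT = object()


def make_snapshot(
    ts: str | datetime,
    position: tuple[float, float] | None = ANCHOR,
    activity: dict[str, float] | None = _DEFAULT,
    fix_age_s: float = 0.0,
    battery: float = 0.9,
) -> ContextSnapshot:
    """Build a snapshot directly, bypassing raw-record parsing."""
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts)
    if activity is _DEFAULT:
        activity = {"still": 1.0}
    return ContextSnapshot(
        timestamp=ts.replace(second=0, microsecond=0),
        x_w=day_week_value(ts),
        x_t=time_of_day_value(ts),
        position=position,
        fix_age_s=fix_age_s,
        activity=activity,
        battery=battery,
    )


def make_rule(
    rule_id: str = "r1",
    anchor: tuple[float, float] = ANCHOR,
    location_term: str = "same_place",
    day_terms=("weekday",),
    time_terms=("morning",),
    activities=("still",),
    availability: dict | None = None,
) -> SituationRule:
    return SituationRule(
        id=rule_id,
        name=rule_id,
        anchor=GeoPoint(lat=anchor[0], lon=anchor[1]),
        location_term=location_term,
        day_terms=frozenset(day_terms),
        time_terms=frozenset(time_terms),
        activities=frozenset(activities),
        availability=availability or {},
    )


@pytest.fixture
def snapshot_factory():
    return make_snapshot


@pytest.fixture
def rule_factory():
    return make_rule
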