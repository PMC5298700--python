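"""Membership functions and fuzzification of smartphone context.

Crisp context values — clock time, day of week, distance from a
registered geographic point, and activity-recognition probabilities —
are mapped onto linguistic terms ("morning", "weekend", "near",
"on activity") through piecewise-linear membership functions.  Time and
day-of-week sets live on cyclic domains (period 24 h and 7 days), so the
"night" and "weekend" sets wrap across midnight and across the
Saturday/Sunday boundary; the wrapped set is the pointwise maximum of
its two non-wrapped pieces, which on a cyclic piecewise-linear
representation is simply the function evaluated modulo the period.

Conventions
-----------
* Day-of-week value ``x_w`` lives in [0, 7): Sunday = 0, Saturday = 6,
  plus the elapsed fraction of the day (minute resolution).
* Time-of-day value ``x_t`` lives in [0, 24): hour plus minute/60,
  seconds discarded.
* Distances are metres from the rule's anchor point.
* Activity probabilities are normalized to [0, 1] from the 0-100 scale
  reported by mobile activity-recognition APIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ACTIVITY_CLASSES",
    "LOCATION_TERMS",
    "DAY_TERMS",
    "TIME_TERMS",
    "FuzzySetSpec",
    "FuzzyVocabulary",
    "standard_vocabulary",
    "eval_membership",
    "location_truth",
    "day_week_value",
    "time_of_day_value",
    "activity_input",
]

#: The seven activity classes reported by the activity-recognition API.
ACTIVITY_CLASSES: tuple[str, ...] = (
    "in_vehicle",
    "on_bicycle",
    "on_foot",
    "running",
    "still",
    "tilting",
    "walking",
)

LOCATION_TERMS: tuple[str, ...] = ("same_place", "near", "different")
DAY_TERMS: tuple[str, ...] = ("weekday", "weekend")
TIME_TERMS: tuple[str, ...] = ("dawn", "morning", "afternoon", "night")

_DOMAINS = {
    "day_of_week": 7.0,
    "time_of_day": 24.0,
    "distance_m": None,
    "activity_level": None,
}


@dataclass(frozen=True)
class FuzzySetSpec:
    """A named piecewise-linear membership function.

    Parameters
    ----------
    name:
        Linguistic label of the set ("morning", "near", ...).
    domain:
        One of ``day_of_week`` ([0, 7)), ``time_of_day`` ([0, 24)),
        ``distance_m`` ([0, inf)) or ``activity_level`` ([0, 1]).
    breakpoints:
        Ordered ``(x, mu)`` vertices.  Between consecutive vertices the
        membership is linear; on non-cyclic domains it is constant
        beyond the extreme vertices, on cyclic domains the function
        wraps with the domain period (the segment from the last vertex
        to the first vertex shifted by one period closes the cycle).
    cyclic:
        Whether the domain wraps (period 7 for day-of-week, 24 for
        time-of-day).
    """

    name: str
    domain: str
    breakpoints: tuple[tuple[float, float], ...]
    cyclic: bool = False

    def __post_init__(self) -> None:
        if self.domain not in _DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.cyclic and _DOMAINS[self.domain] is None:
            raise ValueError(f"domain {self.domain!r} has no period")
        if not self.breakpoints:
            raise ValueError("at least one breakpoint is required")
        xs = [x for x, _ in self.breakpoints]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("breakpoint abscissae must be strictly increasing")
        if any(not 0.0 <= mu <= 1.0 for _, mu in self.breakpoints):
            raise ValueError("membership values must lie in [0, 1]")
        if self.cyclic and (xs[0] < 0 or xs[-1] >= self.period):
            raise ValueError("cyclic breakpoints must lie inside one period")
        object.__setattr__(
            self, "breakpoints", tuple((float(x), float(m)) for x, m in self.breakpoints)
        )

    @property
    def period(self) -> float | None:
        return _DOMAINS[self.domain]

    def __call__(self, x: float) -> float:
        return eval_membership(self, x)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "domain": self.domain,
            "cyclic": self.cyclic,
            "breakpoints": [list(bp) for bp in self.breakpoints],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzySetSpec":
        return cls(
            name=d["name"],
            domain=d["domain"],
            cyclic=bool(d.get("cyclic", False)),
            breakpoints=tuple((float(x), float(m)) for x, m in d["breakpoints"]),
        )


def eval_membership(spec: FuzzySetSpec, x: float) -> float:
    """Evaluate ``spec``'s membership function at ``x``.

    On cyclic domains ``x`` is reduced modulo the period first, so
    mu(x) == mu(x + period) holds exactly.  Beyond the extreme
    breakpoints of a non-cyclic set the membership is constant.
    """
    x = float(x)
    if math.isnan(x) or math.isinf(x):
        raise ValueError(f"membership input must be finite, got {x!r}")
    xs = np.array([p for p, _ in spec.breakpoints])
    mus = np.array([m for _, m in spec.breakpoints])
    if spec.cyclic:
        period = spec.period
        x = x % period
        # close the cycle: repeat the extreme vertices shifted by one period
        xs = np.concatenate(([xs[-1] - period], xs, [xs[0] + period]))
        mus = np.concatenate(([mus[-1]], mus, [mus[0]]))
    return float(np.interp(x, xs, mus))


# ---------------------------------------------------------------------------
# The standard vocabulary
# ---------------------------------------------------------------------------

def _standard_sets() -> dict[str, FuzzySetSpec]:
    """Build the standard linguistic sets.

    Night and weekend follow the engine's printed breakpoints exactly:

    * night   mu = 1 on (21, 24] U [0, 1], ramps 19->21 up and 1->3 down,
      0 on (3, 19];
    * weekend mu = 1 on (6.3, 7) U [0, 0.7], ramps 5.7->6.3 up and
      0.7->1.3 down, 0 on (1.3, 5.7].

    Weekday is the complement 1 - weekend, so its full-membership
    interval is (1.3, 5.7] — Monday morning through Friday afternoon.
    Dawn/morning/afternoon are trapezoids with 2-hour ramps whose
    plateaus make adjacent sets cross at 0.5; morning and afternoon
    plateaus are [6, 12] and [14, 17].  Location terms are anchored
    geofence ramps: same-place 1 up to 100 m falling to 0 at 300 m;
    near 1 up to 800 m falling to 0 at 1200 m; different the rising
    complement of near.  "On activity" is the identity on [0, 1].
    """
    mk = FuzzySetSpec
    return {
        # day of week, Sunday = 0
        "weekend": mk("weekend", "day_of_week", ((0.7, 1), (1.3, 0), (5.7, 0), (6.3, 1)), cyclic=True),
        "weekday": mk("weekday", "day_of_week", ((0.7, 0), (1.3, 1), (5.7, 1), (6.3, 0)), cyclic=True),
        # time of day
        "night": mk("night", "time_of_day", ((1, 1), (3, 0), (19, 0), (21, 1)), cyclic=True),
        "dawn": mk("dawn", "time_of_day", ((1, 0), (3, 1), (4, 1), (6, 0)), cyclic=True),
        "morning": mk("morning", "time_of_day", ((4, 0), (6, 1), (12, 1), (14, 0)), cyclic=True),
        "afternoon": mk("afternoon", "time_of_day", ((12, 0), (14, 1), (17, 1), (19, 0)), cyclic=True),
        # geofence distance, metres from the anchor
        "same_place": mk("same_place", "distance_m", ((100, 1), (300, 0))),
        "near": mk("near", "distance_m", ((800, 1), (1200, 0))),
        "different": mk("different", "distance_m", ((800, 0), (1200, 1))),
        # activity
        "on_activity": mk("on_activity", "activity_level", ((0, 0), (1, 1))),
    }


@dataclass(frozen=True)
class FuzzyVocabulary:
    """The engine's linguistic vocabulary: which sets exist per condition.

    The standard vocabulary has 3 location terms, 2 day terms, 4 time
    terms and a single activity set, the basis of the 3 x 4 x 2 x 1 = 24
    distinct rule-antecedent forms.
    """

    sets: Mapping[str, FuzzySetSpec] = field(default_factory=_standard_sets)
    location_terms: tuple[str, ...] = LOCATION_TERMS
    day_terms: tuple[str, ...] = DAY_TERMS
    time_terms: tuple[str, ...] = TIME_TERMS
    activity_classes: tuple[str, ...] = ACTIVITY_CLASSES
    activity_sets: tuple[str, ...] = ("on_activity",)

    def membership(self, name: str, x: float) -> float:
        try:
            spec = self.sets[name]
        except KeyError:
            raise KeyError(f"unknown fuzzy set {name!r}") from None
        return eval_membership(spec, x)

    def to_json_dict(self) -> dict:
        return {
            "sets": [s.to_dict() for s in self.sets.values()],
            "location_terms": list(self.location_terms),
            "day_terms": list(self.day_terms),
            "time_terms": list(self.time_terms),
            "activity_classes": list(self.activity_classes),
            "activity_sets": list(self.activity_sets),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "FuzzyVocabulary":
        sets = {s["name"]: FuzzySetSpec.from_dict(s) for s in d["sets"]}
        return cls(
            sets=sets,
            location_terms=tuple(d["location_terms"]),
            day_terms=tuple(d["day_terms"]),
            time_terms=tuple(d["time_terms"]),
            activity_classes=tuple(d["activity_classes"]),
            activity_sets=tuple(d["activity_sets"]),
        )


_STANDARD = FuzzyVocabulary()


def standard_vocabulary() -> FuzzyVocabulary:
    """Return the standard (shared, immutable) vocabulary."""
    return _STANDARD


# ---------------------------------------------------------------------------
# Fuzzification maps
# ---------------------------------------------------------------------------

def location_truth(term: str, distance_m: float, vocabulary: FuzzyVocabulary | None = None) -> float:
    """Truth of a location term at ``distance_m`` metres from the anchor.

    same_place is a subset of near: a user at the same place is also
    nearby, so mu_same_place(d) <= mu_near(d) for every distance.
    """
    vocab = vocabulary or _STANDARD
    if term not in vocab.location_terms:
        raise KeyError(f"unknown location term {term!r}")
    if distance_m < 0:
        raise ValueError("distance must be non-negative")
    return vocab.membership(term, distance_m)


def _parse_timestamp(ts: datetime | str) -> datetime:
    if isinstance(ts, str):
        try:
            ts = datetime.fromisoformat(ts)
        except ValueError as exc:
            raise ValueError(f"unparseable timestamp {ts!r}") from exc
    if not isinstance(ts, datetime):
        raise TypeError(f"expected datetime or ISO string, got {type(ts).__name__}")
    return ts


def day_week_value(ts: datetime | str) -> float:
    """Day-of-week coordinate in [0, 7), Sunday = 0.

    The integer part indexes the day (Sunday 0 ... Saturday 6); the
    fractional part is the elapsed fraction of the day at minute
    resolution, so 24 h span one unit.
    """
    ts = _parse_timestamp(ts)
    day = (ts.weekday() + 1) % 7  # datetime: Monday=0 -> our Sunday=0
    return day + (ts.hour * 60 + ts.minute) / 1440.0


def time_of_day_value(ts: datetime | str) -> float:
    """Time-of-day coordinate in [0, 24): hour + minute/60, seconds dropped."""
    ts = _parse_timestamp(ts)
    return ts.hour + ts.minute / 60.0


def activity_input(
    probabilities: Mapping[str, float] | Sequence[float],
    selected: Iterable[str],
) -> float:
    """Crisp input to the "on activity" set.

    Sums the normalized probabilities of the activity classes selected
    in the rule and caps the sum at one: classes are not mutually
    exclusive (walking inside a moving vehicle, "on foot" subsuming
    walking and running), so the raw sum can exceed full certainty.

    ``probabilities`` may be a class->value mapping or a sequence of 7
    values in :data:`ACTIVITY_CLASSES` order; values must be in [0, 1].
    """
    if isinstance(probabilities, Mapping):
        probs = {c: float(probabilities.get(c, 0.0)) for c in ACTIVITY_CLASSES}
        unknown = set(probabilities) - set(ACTIVITY_CLASSES)
        if unknown:
            raise KeyError(f"unknown activity classes {sorted(unknown)}")
    else:
        vals = list(probabilities)
        if len(vals) != len(ACTIVITY_CLASSES):
            raise ValueError(f"expected {len(ACTIVITY_CLASSES)} probabilities, got {len(vals)}")
        probs = dict(zip(ACTIVITY_CLASSES, map(float, vals)))
    sel = list(selected)
    if not sel:
        raise ValueError("at least one activity class must be selected")
    unknown = set(sel) - set(ACTIVITY_CLASSES)
    if unknown:
        raise KeyError(f"unknown activity classes {sorted(unknown)}")
    for c, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {c!r} outside [0, 1]: {p}")
    return min(1.0, sum(probs[c] for c in set(sel)))
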