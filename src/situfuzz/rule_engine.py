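"""Situation fuzzy rules and their per-rule max-product evaluation.

A situation is a tuple <L, T, A>: a location term relative to a
user-registered anchor point, time terms (day-of-week and time-of-day),
and a subset of activity classes.  Each rule is evaluated individually
against the current context snapshot — disjunctions inside a condition
("morning or afternoon", the two wrapped pieces of "night") combine by
maximum, and the antecedent conjunction combines by product, so the
degree of activation reflects every condition's truth at once.

Because rules are evaluated one by one with their own anchor and
activity selection as inputs, many situations can share the same
linguistic form (e.g. two "same place on weekday mornings" rules for
workplace and gym) and still activate differently; the vocabulary
itself admits only 3 x 4 x 2 x 1 = 24 distinct antecedent forms.

Defining two rules identical except that one says "same place" and the
other "near" (same anchor) creates a *case of doubt*: within 100 m of
the anchor both activate equally.  Adding the second such rule raises
:class:`CaseOfDoubtError` so it can be changed, or kept with an
explicit override, in which case both situations are identified
simultaneously.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

from .context_provider import ContextSnapshot, DEFAULT_STALE_HORIZON_S, location_confidence
from .fuzzy_core import (
    ACTIVITY_CLASSES,
    DAY_TERMS,
    LOCATION_TERMS,
    TIME_TERMS,
    FuzzyVocabulary,
    activity_input,
    location_truth,
    standard_vocabulary,
)

__all__ = [
    "NOTIFICATION_TYPES",
    "GeoPoint",
    "SituationRule",
    "ActivationResult",
    "InferenceSuspended",
    "CaseOfDoubtError",
    "DuplicateRuleError",
    "UnknownRuleError",
    "RuleStore",
    "haversine_m",
    "evaluate_rule",
    "get_active_situations",
    "current_situation",
    "enumerate_antecedent_forms",
]

#: The six self-assessment notification types a situation maps to an
#: allowed/denied verdict.
NOTIFICATION_TYPES: tuple[str, ...] = (
    "anxiety_level",
    "mood_rate",
    "positivity_of_thoughts",
    "self_efficacy",
    "motivation",
    "sleep_quality",
)

_EARTH_RADIUS_M = 6_371_008.8


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres between two WGS-84 points.

    At the sub-kilometre scales of a geofence this agrees with planar
    Euclidean distance to within centimetres.
    """
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * _EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


class InferenceSuspended(RuntimeError):
    """Raised when the snapshot lacks location or activity data.

    Inference is declined rather than silently reporting a zero degree;
    the scheduler turns a sustained suspension into an `unavailable`
    event for the prompting client.
    """


class CaseOfDoubtError(ValueError):
    """Adding this rule duplicates an existing one up to same_place/near."""

    def __init__(self, new_rule_id: str, existing_rule_id: str):
        super().__init__(
            f"rule {new_rule_id!r} differs from {existing_rule_id!r} only in "
            "same_place vs near: within 100 m of the anchor both activate "
            "equally (pass override_doubt=True to keep it)"
        )
        self.new_rule_id = new_rule_id
        self.existing_rule_id = existing_rule_id


class DuplicateRuleError(ValueError):
    pass


class UnknownRuleError(KeyError):
    pass


class GeoPoint(BaseModel):
    lat: float = Field(ge=-90, le=90)
    lon: float = Field(ge=-180, le=180)


class SituationRule(BaseModel):
    """A user-defined situation: anchor, linguistic terms, availability map."""

    id: str
    name: str
    anchor: GeoPoint
    location_term: Literal["same_place", "near", "different"]
    day_terms: frozenset[str]
    time_terms: frozenset[str]
    activities: frozenset[str]
    availability: dict[str, bool] = Field(default_factory=dict)

    @field_validator("day_terms")
    @classmethod
    def _day(cls, v):
        return _check_subset(v, DAY_TERMS, "day term")

    @field_validator("time_terms")
    @classmethod
    def _time(cls, v):
        return _check_subset(v, TIME_TERMS, "time term")

    @field_validator("activities")
    @classmethod
    def _act(cls, v):
        return _check_subset(v, ACTIVITY_CLASSES, "activity class")

    @model_validator(mode="after")
    def _fill_availability(self):
        unknown = set(self.availability) - set(NOTIFICATION_TYPES)
        if unknown:
            raise ValueError(f"unknown notification types {sorted(unknown)}")
        full = {t: bool(self.availability.get(t, True)) for t in NOTIFICATION_TYPES}
        object.__setattr__(self, "availability", full)
        return self


def _check_subset(v: frozenset[str], allowed: Sequence[str], what: str) -> frozenset[str]:
    if not v:
        raise ValueError(f"at least one {what} is required")
    unknown = set(v) - set(allowed)
    if unknown:
        raise ValueError(f"unknown {what}s {sorted(unknown)}")
    return frozenset(v)


@dataclass(frozen=True)
class ActivationResult:
    """Per-rule degree of activation with the four condition truths."""

    rule_id: str
    degree: float
    condition_truths: dict[str, float]  # keys: location, day, time, activity
    evaluated_at: datetime


def evaluate_rule(
    rule: SituationRule,
    snapshot: ContextSnapshot,
    vocabulary: FuzzyVocabulary | None = None,
    stale_horizon_s: float = DEFAULT_STALE_HORIZON_S,
) -> ActivationResult:
    """Degree of activation of one rule on one snapshot.

    Condition truths:

    * location — membership of the rule's term at the great-circle
      distance from the snapshot position to the anchor, multiplied by
      the staleness confidence of the fix;
    * day — max over the rule's day terms at ``x_w``;
    * time — max over the rule's time terms at ``x_t`` (cyclic sets
      such as night already cover both wrapped pieces);
    * activity — "on activity" membership of the capped probability sum
      over the rule's selected classes.

    The degree is the product of the four truths.  Raises
    :class:`InferenceSuspended` when the snapshot has no position or no
    activity vector.
    """
    vocab = vocabulary or standard_vocabulary()
    if snapshot.position is None:
        raise InferenceSuspended("no location fix in snapshot")
    if snapshot.activity is None:
        raise InferenceSuspended("no activity data in snapshot")

    distance = haversine_m(snapshot.position[0], snapshot.position[1], rule.anchor.lat, rule.anchor.lon)
    loc = location_truth(rule.location_term, distance, vocab) * location_confidence(
        snapshot.fix_age_s, stale_horizon_s
    )
    day = max(vocab.membership(t, snapshot.x_w) for t in rule.day_terms)
    tod = max(vocab.membership(t, snapshot.x_t) for t in rule.time_terms)
    act = vocab.membership("on_activity", activity_input(snapshot.activity, rule.activities))
    truths = {"location": loc, "day": day, "time": tod, "activity": act}
    degree = loc * day * tod * act
    return ActivationResult(
        rule_id=rule.id,
        degree=degree,
        condition_truths=truths,
        evaluated_at=snapshot.timestamp,
    )


def get_active_situations(
    rules: Iterable[SituationRule],
    snapshot: ContextSnapshot,
    vocabulary: FuzzyVocabulary | None = None,
    stale_horizon_s: float = DEFAULT_STALE_HORIZON_S,
) -> list[ActivationResult]:
    """All rules with degree > 0, sorted by degree descending (id tie-break)."""
    results = [
        evaluate_rule(r, snapshot, vocabulary, stale_horizon_s) for r in rules
    ]
    active = [r for r in results if r.degree > 0.0]
    return sorted(active, key=lambda r: (-r.degree, r.rule_id))


def current_situation(
    rules: Iterable[SituationRule],
    snapshot: ContextSnapshot,
    vocabulary: FuzzyVocabulary | None = None,
    stale_horizon_s: float = DEFAULT_STALE_HORIZON_S,
) -> frozenset[str]:
    """Ids of the maximally activated situations (empty when none fire).

    Rules tying at the maximal degree — the deliberate "case of doubt"
    configuration, or any coincidence — are all reported: the engine
    identifies them simultaneously rather than picking arbitrarily.
    """
    active = get_active_situations(rules, snapshot, vocabulary, stale_horizon_s)
    if not active:
        return frozenset()
    top = active[0].degree
    return frozenset(r.rule_id for r in active if r.degree == top)


def enumerate_antecedent_forms(vocabulary: FuzzyVocabulary | None = None) -> int:
    """Number of distinct antecedent forms the vocabulary admits.

    One term per condition: location x time x day x activity-set.  The
    standard vocabulary gives 3 x 4 x 2 x 1 = 24.
    """
    vocab = vocabulary or standard_vocabulary()
    forms = list(
        itertools.product(
            vocab.location_terms, vocab.time_terms, vocab.day_terms, vocab.activity_sets
        )
    )
    return len(forms)


# ---------------------------------------------------------------------------
# Rule persistence
# ---------------------------------------------------------------------------

_DOUBT_PAIR = frozenset({"same_place", "near"})
_DOUBT_ANCHOR_TOL_M = 1.0  # float round-trip through JSON

SCHEMA_VERSION = 1


def _rule_json_dict(rule: SituationRule) -> dict:
    d = rule.model_dump(mode="json")
    for key in ("day_terms", "time_terms", "activities"):
        d[key] = sorted(d[key])  # frozensets serialize in arbitrary order
    return d


class RuleStore:
    """In-memory rule set with JSON persistence and doubt detection."""

    def __init__(self, rules: Iterable[SituationRule] = ()):  # noqa: D107
        self._rules: dict[str, SituationRule] = {}
        for r in rules:
            self.add(r, override_doubt=True)

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        return iter(self._rules.values())

    def __contains__(self, rule_id: str) -> bool:
        return rule_id in self._rules

    def get(self, rule_id: str) -> SituationRule:
        try:
            return self._rules[rule_id]
        except KeyError:
            raise UnknownRuleError(rule_id) from None

    def all(self) -> list[SituationRule]:
        return list(self._rules.values())

    def add(self, rule: SituationRule, override_doubt: bool = False) -> str:
        """Store a rule; raise :class:`CaseOfDoubtError` on a same_place/near twin.

        The doubt check compares anchors with a 1 m tolerance and
        requires identical day, time and activity terms.  With
        ``override_doubt`` the rule is kept and the twin situations will
        be identified simultaneously within 100 m of the anchor.
        """
        if rule.id in self._rules:
            raise DuplicateRuleError(f"rule id {rule.id!r} already stored")
        if not override_doubt:
            twin = self._find_doubt_twin(rule)
            if twin is not None:
                raise CaseOfDoubtError(rule.id, twin.id)
        self._rules[rule.id] = rule
        return rule.id

    def _find_doubt_twin(self, rule: SituationRule) -> Optional[SituationRule]:
        for other in self._rules.values():
            if {rule.location_term, other.location_term} != _DOUBT_PAIR:
                continue
            if (
                rule.day_terms == other.day_terms
                and rule.time_terms == other.time_terms
                and rule.activities == other.activities
                and haversine_m(
                    rule.anchor.lat, rule.anchor.lon, other.anchor.lat, other.anchor.lon
                )
                <= _DOUBT_ANCHOR_TOL_M
            ):
                return other
        return None

    def remove(self, rule_id: str) -> SituationRule:
        """Remove and return a rule; history referencing it is untouched."""
        try:
            return self._rules.pop(rule_id)
        except KeyError:
            raise UnknownRuleError(rule_id) from None

    # -- persistence --------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "rules": [_rule_json_dict(r) for r in self._rules.values()],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")

    @classmethod
    def from_json_dict(cls, d: dict) -> "RuleStore":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported rules schema version {version}")
        return cls(SituationRule.model_validate(r) for r in d.get("rules", []))

    @classmethod
    def load(cls, path: str | Path) -> "RuleStore":
        return cls.from_json_dict(json.loads(Path(path).read_text()))
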