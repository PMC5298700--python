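"""Per-rule max-product evaluation, selection, and rule maintenance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ANCHOR, make_rule, make_snapshot
from situfuzz import (
    ACTIVITY_CLASSES,
    CaseOfDoubtError,
    DuplicateRuleError,
    FuzzyVocabulary,
    InferenceSuspended,
    RuleStore,
    UnknownRuleError,
    current_situation,
    enumerate_antecedent_forms,
    evaluate_rule,
    get_active_situations,
    haversine_m,
    location_confidence,
    standard_vocabulary,
)

VOCAB = standard_vocabulary()
WED_10 = "2017-01-11T10:00:00"  # Wednesday morning


def offset_east(anchor, metres):
    lat, lon = anchor
    return lat, lon + metres / (111_320.0 * math.cos(math.radians(lat)))


class TestEvaluateRule:
    def test_all_conditions_true_gives_degree_one(self):
        rule = make_rule()
        snap = make_snapshot(WED_10)
        res = evaluate_rule(rule, snap)
        assert res.degree == 1.0
        assert all(v == 1.0 for v in res.condition_truths.values())

    def test_degree_is_product_of_condition_truths(self):
        # location 0.8 via fix staleness, activity 0.5 via partial probability
        rule = make_rule(activities=("walking",))
        snap = make_snapshot(
            WED_10, fix_age_s=0.2 * 27 * 60, activity={"walking": 0.5}
        )
        res = evaluate_rule(rule, snap)
        t = res.condition_truths
        assert t["location"] == pytest.approx(0.8)
        assert t["activity"] == pytest.approx(0.5)
        assert res.degree == pytest.approx(0.8 * 1 * 1 * 0.5)
        assert res.degree <= min(t.values()) + 1e-12

    def test_worked_rule_reaches_full_activation(self):
        # "near" workplace, weekday, morning or afternoon, walking or running
        rule = make_rule(
            location_term="near",
            time_terms=("morning", "afternoon"),
            activities=("walking", "running"),
        )
        snap = make_snapshot(
            WED_10, position=offset_east(ANCHOR, 400), activity={"walking": 1.0}
        )
        assert evaluate_rule(rule, snap).degree == 1.0

    def test_night_wraps_across_midnight(self):
        rule = make_rule(time_terms=("night",), day_terms=("weekday", "weekend"))
        before = make_snapshot("2017-01-11T23:30:00")
        after = make_snapshot("2017-01-12T00:30:00")
        assert evaluate_rule(rule, before).condition_truths["time"] == 1.0
        assert evaluate_rule(rule, after).condition_truths["time"] == 1.0

    def test_or_within_condition_is_max(self):
        rule = make_rule(time_terms=("morning", "afternoon"))
        snap = make_snapshot("2017-01-11T13:00:00")  # between the plateaus
        t = evaluate_rule(rule, snap).condition_truths["time"]
        assert t == pytest.approx(
            max(VOCAB.membership("morning", 13.0), VOCAB.membership("afternoon", 13.0))
        )
        assert t == pytest.approx(0.5)

    def test_missing_data_suspends_not_zero(self):
        rule = make_rule()
        with pytest.raises(InferenceSuspended):
            evaluate_rule(rule, make_snapshot(WED_10, position=None))
        with pytest.raises(InferenceSuspended):
            evaluate_rule(rule, make_snapshot(WED_10, activity=None))

    def test_stale_fix_never_raises_degree(self):
        rule = make_rule()
        fresh = evaluate_rule(rule, make_snapshot(WED_10, fix_age_s=0)).degree
        stale = evaluate_rule(rule, make_snapshot(WED_10, fix_age_s=600)).degree
        assert stale <= fresh

    def test_naive_loop_oracle_equivalence(self):
        """Expanding every max/product by explicit loops matches the engine."""
        rng = np.random.default_rng(7)
        horizon = 27 * 60.0
        terms = {
            "location": ("same_place", "near", "different"),
            "day": ("weekday", "weekend"),
            "time": ("dawn", "morning", "afternoon", "night"),
        }
        for _ in range(1000):
            rule = make_rule(
                location_term=terms["location"][rng.integers(3)],
                day_terms=tuple(
                    rng.choice(terms["day"], size=rng.integers(1, 3), replace=False)
                ),
                time_terms=tuple(
                    rng.choice(terms["time"], size=rng.integers(1, 5), replace=False)
                ),
                activities=tuple(
                    rng.choice(ACTIVITY_CLASSES, size=rng.integers(1, 8), replace=False)
                ),
            )
            bearing = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0, 2000)
            lat = ANCHOR[0] + dist * np.cos(bearing) / 111_320.0
            lon = ANCHOR[1] + dist * np.sin(bearing) / (
                111_320.0 * math.cos(math.radians(ANCHOR[0]))
            )
            snap = make_snapshot(
                f"2017-01-{int(rng.integers(8, 15)):02d}T"
                f"{int(rng.integers(0, 24)):02d}:{int(rng.integers(0, 60)):02d}:00",
                position=(lat, lon),
                activity={c: float(rng.uniform(0, 1)) for c in ACTIVITY_CLASSES},
                fix_age_s=float(rng.uniform(0, 2000)),
            )
            # naive expansion
            d = haversine_m(lat, lon, rule.anchor.lat, rule.anchor.lon)
            loc = VOCAB.membership(rule.location_term, d) * max(
                0.0, 1.0 - snap.fix_age_s / horizon
            )
            day = 0.0
            for t in rule.day_terms:
                day = max(day, VOCAB.membership(t, snap.x_w))
            tod = 0.0
            for t in rule.time_terms:
                tod = max(tod, VOCAB.membership(t, snap.x_t))
            a = 0.0
            for c in rule.activities:
                a += snap.activity[c]
            act = min(1.0, a)
            expected = loc * day * tod * act
            assert evaluate_rule(rule, snap).degree == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=200)
    def test_product_bounded_by_min(self, a, b, c, d):
        degree = a * b * c * d
        assert degree <= min(a, b, c, d) + 1e-12


class TestSelection:
    def test_active_sorted_and_thresholded(self):
        hit = make_rule("hit")
        miss = make_rule("miss", anchor=offset_east(ANCHOR, 5000))
        weaker = make_rule("weaker", activities=("walking",))
        snap = make_snapshot(WED_10, activity={"still": 1.0, "walking": 0.4})
        active = get_active_situations([miss, weaker, hit], snap)
        assert [r.rule_id for r in active] == ["hit", "weaker"]
        assert active[0].degree > active[1].degree > 0

    def test_no_rules_gives_empty(self):
        assert get_active_situations([], make_snapshot(WED_10)) == []
        assert current_situation([], make_snapshot(WED_10)) == frozenset()

    def test_order_independence(self):
        rules = [make_rule(f"r{i}", anchor=offset_east(ANCHOR, 150 * i)) for i in range(5)]
        snap = make_snapshot(WED_10)
        fwd = get_active_situations(rules, snap)
        rev = get_active_situations(rules[::-1], snap)
        assert [(r.rule_id, r.degree) for r in fwd] == [(r.rule_id, r.degree) for r in rev]

    def test_doubt_pair_identified_simultaneously(self):
        same = make_rule("at_work", location_term="same_place")
        near = make_rule("around_work", location_term="near")
        snap = make_snapshot(WED_10, position=offset_east(ANCHOR, 50))
        assert current_situation([same, near], snap) == {"at_work", "around_work"}

    def test_argmax_singleton(self):
        strong = make_rule("strong")
        weak = make_rule("weak", activities=("walking",))
        snap = make_snapshot(WED_10, activity={"still": 1.0, "walking": 0.3})
        assert current_situation([strong, weak], snap) == {"strong"}

    def test_all_zero_degrees_gives_empty_set(self):
        rule = make_rule(anchor=offset_east(ANCHOR, 5000))
        assert current_situation([rule], make_snapshot(WED_10)) == frozenset()

    def test_distant_anchors_break_symmetry(self):
        a = make_rule("a")
        b = make_rule("b", anchor=(ANCHOR[0] + 10_000 / 111_320.0, ANCHOR[1]))
        snap = make_snapshot(WED_10, position=offset_east(ANCHOR, 50))
        res = {r.rule_id: r.degree for r in get_active_situations([a, b], snap)}
        assert res.get("a", 0) > res.get("b", 0)


class TestRuleStore:
    def test_add_and_round_trip(self, tmp_path):
        store = RuleStore()
        store.add(make_rule("work", availability={"mood_rate": False}))
        path = tmp_path / "rules.json"
        store.save(path)
        back = RuleStore.load(path)
        assert back.get("work") == store.get("work")
        assert back.get("work").availability["mood_rate"] is False
        assert back.get("work").availability["motivation"] is True  # default fill

    def test_doubt_exception_and_override(self):
        store = RuleStore()
        store.add(make_rule("w1", location_term="same_place"))
        twin = make_rule("w2", location_term="near")
        with pytest.raises(CaseOfDoubtError):
            store.add(twin)
        store.add(twin, override_doubt=True)
        assert len(store) == 2

    def test_doubt_requires_identical_terms_and_anchor(self):
        store = RuleStore()
        store.add(make_rule("w1", location_term="same_place"))
        # different anchor (10 m away is within GPS noise but > 1 m tolerance)
        other_anchor = offset_east(ANCHOR, 10)
        store.add(make_rule("w2", location_term="near", anchor=other_anchor))
        # near vs different is not the doubt pair
        store.add(make_rule("w3", location_term="different"))
        assert len(store) == 3

    def test_duplicate_id_rejected(self):
        store = RuleStore()
        store.add(make_rule("x"))
        with pytest.raises(DuplicateRuleError):
            store.add(make_rule("x"))

    def test_remove_round_trip(self):
        store = RuleStore()
        store.add(make_rule("keep"))
        before = {r.id for r in store}
        store.add(make_rule("tmp", anchor=offset_east(ANCHOR, 3000)))
        removed = store.remove("tmp")
        assert removed.id == "tmp"
        assert {r.id for r in store} == before
        with pytest.raises(UnknownRuleError):
            store.remove("tmp")

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            make_rule(day_terms=())
        with pytest.raises(ValueError):
            make_rule(time_terms=("brunch",))
        with pytest.raises(ValueError):
            make_rule(availability={"weather": True})


class TestAntecedentEnumeration:
    def test_standard_vocabulary(self):
        assert enumerate_antecedent_forms() == 24

    def test_restricted_vocabulary(self):
        vocab = FuzzyVocabulary(location_terms=("same_place",))
        assert enumerate_antecedent_forms(vocab) == 8

    def test_empty_vocabulary(self):
        vocab = FuzzyVocabulary(location_terms=())
        assert enumerate_antecedent_forms(vocab) == 0


def test_haversine_matches_planar_at_short_range():
    # the 111320 m/deg planar conversion and the spherical radius differ
    # by ~0.1 %, well under the geofence ramp widths
    for metres in (50, 300, 1200):
        p = offset_east(ANCHOR, metres)
        d = haversine_m(ANCHOR[0], ANCHOR[1], p[0], p[1])
        assert d == pytest.approx(metres, rel=2e-3)


def test_location_confidence_decay():
    horizon = 27 * 60.0
    assert location_confidence(0, horizon) == 1.0
    assert location_confidence(horizon / 2, horizon) == pytest.approx(0.5)
    assert location_confidence(horizon, horizon) == 0.0
    assert location_confidence(2 * horizon, horizon) == 0.0
    with pytest.raises(ValueError):
        location_confidence(-1, horizon)
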