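# situfuzz

Fuzzy situation inference from smartphone context, for situation-aware
ecological momentary assessment (EMA).

Mobile mental-health applications prompt patients for in-the-moment
self-reports (mood, anxiety, sleep quality, ...). Prompting at fixed or
random times is intrusive and misses context; prompting by *situation* —
user-named daily-routine states such as "working", "at the gym",
"relaxing at home" — lets the patient and clinician decide which
assessments are welcome in which situation. `situfuzz` implements the
inference engine for that scheme: situations are fuzzy rules over
location, day of week, time of day and physical activity, defined
jointly by patient and clinician rather than learned from data, so the
engine needs no training phase and runs entirely on device-scale inputs.

## The model

A situation is a tuple **S = ⟨L, T, A⟩**:

* **L** — a geofence term relative to a user-registered anchor point:
  *same place* (μ = 1 up to 100 m, linearly to 0 at 300 m), *near*
  (μ = 1 up to 800 m, to 0 at 1200 m) or *different* (the rising
  complement of *near*). *Same place* is a pointwise subset of *near*.
* **T** — day-of-week terms on the cyclic coordinate x_w ∈ [0, 7)
  (Sunday = 0) and time-of-day terms on x_t ∈ [0, 24). *Weekend* and
  *night* wrap across the week and day boundaries; each wrapped set is
  the maximum of its two non-wrapped pieces. *Weekday* is 1 − *weekend*,
  full on (1.3, 5.7]; *morning* and *afternoon* are trapezoids with
  plateaus [6, 12] and [14, 17].
* **A** — a subset of the seven activity-recognition classes
  (in vehicle, on bicycle, on foot, running, still, tilting, walking).
  The crisp input is the capped sum min(1, Σ α_i) of the selected
  classes' normalized probabilities.

Each rule is evaluated individually by **max-product composition**:
disjunctions within a condition combine by max, and the degree of
activation is the *product* of the four condition truths, so every
condition influences the result. The location truth is additionally
multiplied by a staleness confidence max(0, 1 − age/horizon) of the GPS
fix. The *current situation* is the argmax set over all rules with
degree > 0 (ties are reported simultaneously).

Around the engine sit: an energy-aware scheduler (inference every
3/6/9 min with 35/45/60 s sensor warm-ups by battery tier, and an
`unavailable` callback after 27 min of missing context data), a
transition history with summary queries and a notification-availability
API (`addSituation`, `removeSituation`, `getActiveSituations`,
`getAllSituations`, `getSituationsSummary`, `checkStatus`), and a
synthetic daily-routine generator for end-to-end evaluation.

## Worked example

```python
from situfuzz import (RawObservation, SituationRule, evaluate_rule, preprocess)
from situfuzz.rule_engine import GeoPoint

rule = SituationRule(
    id="working", name="working",
    anchor=GeoPoint(lat=41.1500, lon=-8.6100),   # the office
    location_term="near",
    day_terms=frozenset({"weekday"}),
    time_terms=frozenset({"morning", "afternoon"}),
    activities=frozenset({"still", "walking"}),
    availability={"mood_rate": True, "sleep_quality": False},
)
raw = RawObservation(
    timestamp="2017-01-11T10:15:42",             # Wednesday mid-morning
    latitude=41.1522, longitude=-8.6055,         # ~449 m from the anchor
    activity={"still": 70.0, "walking": 25.0},   # 0-100 recognition scale
    battery=0.62,
)
res = evaluate_rule(rule, preprocess(raw))
print(round(res.degree, 4))
print({k: round(v, 4) for k, v in res.condition_truths.items()})
```

prints

```
0.95
{'location': 1.0, 'day': 1.0, 'time': 1.0, 'activity': 0.95}
```

449 m is on the *near* plateau and a fresh fix keeps confidence at 1, so
the location truth is 1.0; Wednesday 10:15 is fully weekday and fully
morning; the selected activity probabilities sum to 0.95. The product —
the degree of activation, the "95 %" a confirmation prompt would show —
is 0.95. `checkStatus("mood_rate")` would answer *allowed* in this
situation and `checkStatus("sleep_quality")` *denied*.

The same flow from the shell:

```bash
situfuzz simulate --seed 3 --out trace.csv --labels-out labels.csv
situfuzz evaluate --trace trace.csv --labels labels.csv --rules rules.json
situfuzz confirmations --log confirmations.csv
```

`confirmations` on the bundled 12-participant field-study counts
(`example_confirmation_counts()`) ends with:

```
overall: 451/490 correct (92.04%)
```

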