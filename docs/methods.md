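# Methods

This note documents the model implemented by `situfuzz`, the choices
made where the design was genuinely open, and what the synthetic
evaluation does and does not demonstrate.

## Inference model

A situation rule is a conjunction of four conditions — location, day of
week, time of day, activity — each fuzzified by piecewise-linear
membership functions. Evaluation is per rule ("adapted" with respect to
a classical rule block): every rule carries its own anchor point and
activity selection as inputs, so rules sharing the same linguistic form
still activate differently. Within a condition, multiple selected terms
combine by maximum (standard fuzzy disjunction; the wrapped pieces of
*night* and *weekend* are the canonical case). Across conditions the
degree of activation is the product of the four truths (max-product
composition), chosen so that no single saturated condition can mask a
weak one — the degree is always bounded above by the minimum condition
truth. The engine outputs rule activations and an argmax set; there is
no defuzzification step, because the consumer needs a ranked set of
situations, not a crisp control value.

### Membership functions

Cyclic sets are stored as breakpoints inside one period and evaluated
modulo the period, which realizes the wrapped plateaus exactly:

| set | domain | shape |
|---|---|---|
| weekend | [0, 7), cyclic | 1 on (6.3, 7)∪[0, 0.7], ramps 5.7→6.3 and 0.7→1.3, else 0 |
| weekday | [0, 7), cyclic | 1 − weekend; full on (1.3, 5.7] |
| night | [0, 24), cyclic | 1 on (21, 24]∪[0, 1], ramps 19→21 and 1→3, else 0 |
| dawn | [0, 24), cyclic | ramp 1→3, plateau [3, 4], ramp 4→6 |
| morning | [0, 24), cyclic | ramp 4→6, plateau [6, 12], ramp 12→14 |
| afternoon | [0, 24), cyclic | ramp 12→14, plateau [14, 17], ramp 17→19 |
| same_place | distance, m | 1 on [0, 100], ramp to 0 at 300 |
| near | distance, m | 1 on [0, 800], ramp to 0 at 1200 |
| different | distance, m | 0 on [0, 800], ramp to 1 at 1200 |
| on_activity | [0, 1] | identity |

Open shape decisions and their rationale:

* **Weekday as the exact complement of weekend.** This pins its
  full-membership interval to (1.3, 5.7] — Monday morning through
  Friday evening — and gives the invariant weekday(x) + weekend(x) = 1
  everywhere, which the tests assert.
* **Dawn/morning/afternoon trapezoids with 2-hour ramps.** The plateau
  edges (6–12 and 14–17) are fixed by the model's stated full-activation
  windows; 2-hour ramps mirror night's ramps and make adjacent sets
  cross at 0.5, so the time condition never has a dead zone between
  named periods.
* **"On activity" as the identity on [0, 1].** The simplest monotone
  map consistent with "higher probability ⇒ more likely correct"; any
  strictly monotone reshaping would only rescale degrees without
  changing argmax sets for rules with equal activity inputs.
* **Continuous distance ramps.** The same-place plateau ends at 100 m
  and the ramp runs linearly from (100, 1) to (300, 0); a 1 m step
  would be far below GPS precision and would break continuity.
* **Activity probabilities** are divided by 100 and *not* renormalized
  across classes — classes are not mutually exclusive ("on foot"
  subsumes walking and running), which is exactly why the selected-class
  sum is capped at 1 rather than forced to be a distribution.

### Distance and staleness

Anchor-to-position distance is the haversine great-circle distance
(sphere radius 6 371 008.8 m); at geofence scales this matches planar
Euclidean distance to within ~0.1 %, far below the 200–400 m ramp
widths. Location-fix staleness multiplies the location truth by
max(0, 1 − age/horizon). The decay form is an open choice; linear decay
with a 27-minute default horizon was chosen so that confidence is
exhausted exactly when the scheduler would declare inference stopped
anyway. Only location decays: activity data are sampled at retrieval
time and have no analogous fix age.

### Ties and the case of doubt

`current_situation` returns the full argmax set rather than an
arbitrary single rule: simultaneous identification is an explicit
feature of the same_place ⊂ near design. At definition time, a rule
identical to a stored one except for the same_place/near pair (anchors
within 1 m — a tolerance covering float round-trips through JSON —
and identical day/time/activity terms) raises a case-of-doubt
exception; an override flag stores it anyway. The near/different pair
does not trigger the exception: those sets are disjoint on the
full-membership plateaus, so the systematic tie the exception guards
against cannot arise.

## Scheduler semantics

Inference ticks are spaced by the battery-dependent interval (3, 6 or
9 min); sensor warm-up (35, 45 or 60 s) precedes each retrieval and is
recorded per tick but does not shift tick spacing — warm-up happens
inside the interval. Battery tier cutoffs are configurable; defaults
are high > 0.5 > mid ≥ 0.2 > low. The unavailability cutoff is a fixed
27 minutes — three times the *largest* interval, not three times the
current one — measured from the first suspended tick; the `unavailable`
event fires at the first tick at or past the cutoff, and the first
successful inference afterwards fires `available`, so events strictly
alternate. The loop runs on simulated time over the trace's own
timestamps and is fully deterministic. The prompting client's
mode-switch behaviour (situation-aware vs fixed-time) is represented by
a small stub that consumes the event stream and logs its mode; it is a
contract reference, not an assessment application.

Each tick evaluates the most recent observation at or before the tick
time ("collected immediately before inference"); observations between
ticks are not buffered or aggregated.

## History and status

The store records only *changes* of the argmax set (strictly
time-ordered transition log); the per-tick sequence is reconstructable
exactly, which the tests verify by replay. `checkStatus` is
conservative under ties: a notification type is allowed only if every
currently identified situation allows it, denied if any denies, and
unavailable when inference is suspended or no situation is identified —
the empty-argmax state cannot justify a situation-aware prompt, so the
client should fall back to fixed times.

## Synthetic evaluation

No public labelled corpus of this kind of context trace exists, so
evaluation uses a generative stand-in. A scenario is a set of named
places and a schedule of episodes (window, place, activity mixture,
intended situation label). The generator emits one observation per
minute: position = episode place + isotropic Gaussian noise (σ in
metres, default 10 m — a typical open-sky GPS fix), activity
probabilities = mixture weights + Gaussian noise (default σ 0.05 on the
unit scale) with "on foot" derived as the capped sum of walking and
running, battery discharging linearly (default 4 %/h, enough to cross
battery tiers within a day). Between episodes the agent holds the
previous place with an in-vehicle mixture and no label, modelling
commutes without claiming a ground-truth situation for them. Traces are
deterministic given a seed; labels depend only on the schedule.

Scoring mirrors a yes/no confirmation protocol: a tick counts as
correct when its label is in the argmax set, incorrect when some
situation fired but the label is not among them; quiet ticks are
excluded from the headline percentage (only an identified situation can
be confirmed) and tracked as misses or correct negatives.

The reference weekday routine has home, workplace and gym anchors
pairwise ≥ 2 km apart. On it, with 10 m GPS noise and clean activity
probabilities, the engine recovers ≥ 95 % of labelled ticks across 20
seeds, and median accuracy degrades monotonically as GPS noise sweeps
10 → 200 → 600 → 1500 m (20 seeds per level; the whole sweep is 80
one-day simulations and runs in well under a minute). What this shows:
the inference pipeline is correct end to end and fails gracefully under
position noise. What it does not show: field accuracy. Real routines
have overlapping anchors, indoor GPS loss, activity-classifier bias and
self-selection in which prompts get answered; the bundled
12-participant confirmation counts (490 confirmations, 92.04 % "yes")
are a worked dataset for the log arithmetic, not a claim that the
synthetic conditions reproduce them.

Percentages shown to users are truncated (not rounded) to two decimals;
`analyze_confirmations` reports both the exact value and the display
form.

## Numerical notes

* Membership evaluation is linear interpolation over breakpoints;
  cyclic domains prepend/append the period-shifted extreme vertices, so
  periodicity is exact up to the floating-point modulo reduction
  (error ≤ a few ulps, bounded by the ramps' Lipschitz constants).
* Degrees are exact products of condition truths; the argmax set uses
  exact float equality, which is the right notion here because tied
  rules (the doubt pair) compute their degrees through identical
  arithmetic.
* Timestamps are truncated, not rounded, to the minute, keeping x_t on
  an exact 1/60 grid.

## Limitations

* Rule shapes are fixed; there is no learning or tuning from data, by
  design (the user is the expert).
* The simulator teleports between episodes rather than moving the agent
  along a path; evaluation near geofence boundaries during genuine
  movement is therefore not exercised.
* One "on activity" set serves all rules; per-class weighting inside a
  rule is not expressible beyond selecting the class subset.
* The FCL-style export is write-only and simplified: per-rule anchors
  and activity selections have no native FCL representation and are
  emitted as comments.
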