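"""Energy-aware inference loop over a context trace, on a simulated clock.

Inference runs periodically rather than continuously: every 3, 6 or 9
minutes depending on the battery tier, with the sensing services warmed
up 35, 45 or 60 seconds before each data retrieval (35 s being the
minimum considered safe for fresh activity data).  Ticks evaluate the
rule set on the most recent observation; a tick whose observation lacks
location or activity data suspends inference.  After 27 consecutive
minutes of suspension — three times the largest inference interval —
an ``unavailable`` event is emitted for the prompting client, which is
expected to fall back to fixed-time prompting; the first successful
inference afterwards emits ``available`` and the client switches back.

The loop is event-driven over the trace's own timestamps: no wall-clock
dependence, so replays are deterministic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Literal, Sequence

from .context_provider import (
    DEFAULT_STALE_HORIZON_S,
    RawObservation,
    preprocess,
)
from .rule_engine import SituationRule, get_active_situations
from .situation_store import TransitionLog

__all__ = [
    "BatteryTiers",
    "SchedulerConfig",
    "Event",
    "Tick",
    "inference_interval",
    "warmup_delay",
    "run_loop",
    "PromptModeStub",
]

INTERVALS_MIN = (3, 6, 9)
WARMUPS_S = (35, 45, 60)


@dataclass(frozen=True)
class BatteryTiers:
    """Battery tier cutoffs: high above ``high_above``, low below ``low_below``."""

    high_above: float = 0.5
    low_below: float = 0.2

    def tier(self, battery: float) -> int:
        if not 0.0 <= battery <= 1.0:
            raise ValueError(f"battery level outside [0, 1]: {battery}")
        if battery > self.high_above:
            return 0
        if battery >= self.low_below:
            return 1
        return 2


@dataclass(frozen=True)
class SchedulerConfig:
    tiers: BatteryTiers = field(default_factory=BatteryTiers)
    #: continuous-suspension span after which inference is declared
    #: stopped: three times the largest inference interval.
    stale_cutoff_min: float = 27.0
    stale_horizon_s: float = DEFAULT_STALE_HORIZON_S


def inference_interval(battery: float, tiers: BatteryTiers | None = None) -> int:
    """Minutes between inference runs for this battery level: 3, 6 or 9."""
    tiers = tiers or BatteryTiers()
    return INTERVALS_MIN[tiers.tier(battery)]


def warmup_delay(battery: float, tiers: BatteryTiers | None = None) -> int:
    """Seconds of sensor warm-up before data retrieval: 35, 45 or 60."""
    tiers = tiers or BatteryTiers()
    return WARMUPS_S[tiers.tier(battery)]


@dataclass(frozen=True)
class Event:
    timestamp: datetime
    kind: Literal["unavailable", "available"]


@dataclass(frozen=True)
class Tick:
    """Bookkeeping for one inference run."""

    timestamp: datetime
    warmup_started: datetime
    interval_min: int
    warmup_s: int
    suspended: bool
    situation_ids: frozenset[str]
    degree: float


def run_loop(
    trace: Sequence[RawObservation],
    rules: Iterable[SituationRule],
    config: SchedulerConfig | None = None,
) -> tuple[TransitionLog, list[Event], list[Tick]]:
    """Replay the inference loop over a time-sorted trace.

    Returns the transition log, the availability events (strictly
    alternating, ``unavailable`` first) and the per-tick bookkeeping.
    An empty rule set still runs — suspension/availability semantics
    depend only on data presence — but records no transitions.
    """
    cfg = config or SchedulerConfig()
    trace = list(trace)
    if not trace:
        raise ValueError("empty trace")
    times = [o.timestamp for o in trace]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("trace must be sorted by timestamp")
    rules = list(rules)

    log = TransitionLog()
    events: list[Event] = []
    ticks: list[Tick] = []
    cutoff = timedelta(minutes=cfg.stale_cutoff_min)

    t = times[0]
    end = times[-1]
    suspended_since: datetime | None = None
    unavailable_open = False

    while t <= end:
        # the observation collected immediately before this inference run
        idx = bisect.bisect_right(times, t) - 1
        obs = trace[idx]
        battery = obs.battery
        interval = inference_interval(battery, cfg.tiers)
        warmup = warmup_delay(battery, cfg.tiers)
        snap = preprocess(obs, at=t)

        if snap.position is None or snap.activity is None:
            if suspended_since is None:
                suspended_since = t
            if not unavailable_open and t - suspended_since >= cutoff:
                events.append(Event(t, "unavailable"))
                unavailable_open = True
            ids: frozenset[str] = frozenset()
            degree = 0.0
            suspended = True
        else:
            suspended_since = None
            if unavailable_open:
                events.append(Event(t, "available"))
                unavailable_open = False
            active = get_active_situations(rules, snap, stale_horizon_s=cfg.stale_horizon_s)
            if active:
                top = active[0].degree
                ids = frozenset(r.rule_id for r in active if r.degree == top)
                degree = top
            else:
                ids, degree = frozenset(), 0.0
            if rules:
                log.record_transition(t, ids, degree)
            suspended = False

        ticks.append(
            Tick(
                timestamp=t,
                warmup_started=t - timedelta(seconds=warmup),
                interval_min=interval,
                warmup_s=warmup,
                suspended=suspended,
                situation_ids=ids,
                degree=degree,
            )
        )
        t = t + timedelta(minutes=interval)

    return log, events, ticks


class PromptModeStub:
    """Reference client for the availability contract.

    Tracks which prompting mode the assessment client would be in —
    situation-aware while inference is available, fixed-time after an
    ``unavailable`` event — and logs every switch.  It is a contract
    stub, not an assessment application.
    """

    def __init__(self) -> None:
        self.mode: str = "situation_aware"
        self.switches: list[tuple[datetime, str]] = []

    def on_event(self, event: Event) -> None:
        new_mode = "fixed_time" if event.kind == "unavailable" else "situation_aware"
        if new_mode != self.mode:
            self.mode = new_mode
            self.switches.append((event.timestamp, new_mode))

    def replay(self, events: Iterable[Event]) -> "PromptModeStub":
        for e in events:
            self.on_event(e)
        return self
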