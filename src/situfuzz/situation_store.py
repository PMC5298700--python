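"""Situation history, summary queries and the notification-status API.

The engine only stores *changes* of situation: a transition log whose
records carry a timestamp, the set of maximally activated situation ids
(possibly empty, meaning "no situation identified") and the maximal
degree.  The tick-level situation sequence can always be reconstructed
from the transitions, so the log is a lossless compression of the
inference history.

``check_status`` answers the prompting client's question "may I show
this notification type now?".  Tie policy: when several situations are
simultaneously current (case of doubt, or a genuine tie), a prompt is
allowed only if *every* tied situation allows it — the conservative
reading that minimizes intrusiveness.  When inference is suspended or
no situation is identified, the verdict is "unavailable" and the client
is expected to fall back to fixed-time prompting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Optional

from .context_provider import ContextSnapshot
from .rule_engine import (
    NOTIFICATION_TYPES,
    ActivationResult,
    RuleStore,
    SituationRule,
    get_active_situations,
)

__all__ = [
    "SituationRecord",
    "TransitionLog",
    "AvailabilityStatus",
    "check_status",
    "SituationService",
]


@dataclass(frozen=True)
class SituationRecord:
    """One transition: at ``timestamp`` the current set became ``situation_ids``."""

    timestamp: datetime
    situation_ids: frozenset[str]
    degree: float

    def to_json_dict(self) -> dict:
        return {
            "timestamp": self.timestamp.isoformat(),
            "situation_ids": sorted(self.situation_ids),
            "degree": self.degree,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SituationRecord":
        return cls(
            timestamp=datetime.fromisoformat(d["timestamp"]),
            situation_ids=frozenset(d["situation_ids"]),
            degree=float(d["degree"]),
        )


class TransitionLog:
    """Append-only, strictly time-ordered log of situation transitions."""

    def __init__(self, records: Iterable[SituationRecord] = ()):  # noqa: D107
        self._records: list[SituationRecord] = []
        for r in records:
            self.record_transition(r.timestamp, r.situation_ids, r.degree)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    @property
    def records(self) -> list[SituationRecord]:
        return list(self._records)

    @property
    def last(self) -> Optional[SituationRecord]:
        return self._records[-1] if self._records else None

    def record_transition(
        self, timestamp: datetime, situation_ids: Iterable[str], degree: float
    ) -> bool:
        """Append iff the id set changed since the previous record.

        Returns True when appended, False when skipped as a repeat.
        Timestamps must be strictly increasing.
        """
        ids = frozenset(situation_ids)
        if self._records:
            if timestamp <= self._records[-1].timestamp:
                raise ValueError(
                    f"out-of-order record at {timestamp.isoformat()} "
                    f"(last stored {self._records[-1].timestamp.isoformat()})"
                )
            if ids == self._records[-1].situation_ids:
                return False
        self._records.append(SituationRecord(timestamp, ids, float(degree)))
        return True

    def get_summary(self, t0: datetime, t1: datetime) -> list[SituationRecord]:
        """Records with timestamp in [t0, t1], original order preserved."""
        if t0 > t1:
            raise ValueError("summary window start must not exceed its end")
        return [r for r in self._records if t0 <= r.timestamp <= t1]

    def reconstruct(self, tick_times: Iterable[datetime]) -> list[frozenset[str]]:
        """Per-tick situation sets implied by the transition log."""
        out: list[frozenset[str]] = []
        idx = -1
        for t in tick_times:
            while idx + 1 < len(self._records) and self._records[idx + 1].timestamp <= t:
                idx += 1
            out.append(self._records[idx].situation_ids if idx >= 0 else frozenset())
        return out

    # -- persistence --------------------------------------------------------

    def save_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self._records:
                fh.write(json.dumps(r.to_json_dict()) + "\n")

    @classmethod
    def load_jsonl(cls, path: str | Path) -> "TransitionLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    r = SituationRecord.from_json_dict(json.loads(line))
                    log.record_transition(r.timestamp, r.situation_ids, r.degree)
        return log

    def save_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "timestamp": r.timestamp.isoformat(),
                    "situations": ";".join(sorted(r.situation_ids)),
                    "degree": r.degree,
                }
                for r in self._records
            ],
            columns=["timestamp", "situations", "degree"],
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class AvailabilityStatus:
    notification_type: str
    verdict: Literal["allowed", "denied", "unavailable"]


def check_status(
    notification_type: str,
    current_rules: Iterable[SituationRule],
    suspended: bool = False,
) -> AvailabilityStatus:
    """Availability verdict for one notification type.

    ``current_rules`` are the rules in the current argmax set.  Verdict
    is "unavailable" when inference is suspended or no situation is
    current; "denied" when any current situation denies the type;
    "allowed" only when every current situation allows it.
    """
    if notification_type not in NOTIFICATION_TYPES:
        raise KeyError(f"unknown notification type {notification_type!r}")
    rules = list(current_rules)
    if suspended or not rules:
        return AvailabilityStatus(notification_type, "unavailable")
    if all(r.availability[notification_type] for r in rules):
        return AvailabilityStatus(notification_type, "allowed")
    return AvailabilityStatus(notification_type, "denied")


class SituationService:
    """Facade bundling rules, history and status into one service object.

    Method names mirror the service interface a client application
    binds to: ``addSituation``, ``removeSituation``,
    ``getActiveSituations``, ``getAllSituations``,
    ``getSituationsSummary`` and ``checkStatus``.
    """

    def __init__(self, rules: RuleStore | None = None, log: TransitionLog | None = None):
        self.rules = rules if rules is not None else RuleStore()
        self.log = log if log is not None else TransitionLog()
        self.suspended: bool = False
        self._current: frozenset[str] = frozenset()

    # -- rule maintenance ---------------------------------------------------

    def addSituation(self, rule: SituationRule, override_doubt: bool = False) -> str:  # noqa: N802
        return self.rules.add(rule, override_doubt=override_doubt)

    def removeSituation(self, rule_id: str) -> SituationRule:  # noqa: N802
        return self.rules.remove(rule_id)

    def getAllSituations(self) -> list[SituationRule]:  # noqa: N802
        return self.rules.all()

    # -- inference ----------------------------------------------------------

    def getActiveSituations(self, snapshot: ContextSnapshot) -> list[ActivationResult]:  # noqa: N802
        return get_active_situations(self.rules, snapshot)

    def observe(self, snapshot: ContextSnapshot) -> frozenset[str]:
        """Run inference on a snapshot, updating history and current set."""
        active = self.getActiveSituations(snapshot)
        self.suspended = False
        ids = (
            frozenset(r.rule_id for r in active if r.degree == active[0].degree)
            if active
            else frozenset()
        )
        degree = active[0].degree if active else 0.0
        self._current = ids
        if len(self.rules):
            self.log.record_transition(snapshot.timestamp, ids, degree)
        return ids

    def suspend(self) -> None:
        self.suspended = True
        self._current = frozenset()

    @property
    def currentSituation(self) -> frozenset[str]:  # noqa: N802
        return self._current

    # -- queries ------------------------------------------------------------

    def getSituationsSummary(self, t0: datetime, t1: datetime) -> list[SituationRecord]:  # noqa: N802
        return self.log.get_summary(t0, t1)

    def checkStatus(self, notification_type: str) -> AvailabilityStatus:  # noqa: N802
        current_rules = [self.rules.get(i) for i in self._current if i in self.rules]
        return check_status(notification_type, current_rules, suspended=self.suspended)
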