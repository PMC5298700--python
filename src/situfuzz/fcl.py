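"""Write-only export of the vocabulary and rules to an FCL-style text block.

Fuzzy Control Language (IEC 61131-7) is the interchange format many
fuzzy-logic toolkits read.  This is a simplified dialect intended for
inspection and interoperability, not a round-trip serialization: the
engine's per-rule anchored evaluation (each rule carries its own
geographic anchor and activity selection) has no native FCL equivalent,
so anchors and activity selections are emitted as comments on the rule.
"""

from __future__ import annotations

from typing import Iterable

from .fuzzy_core import FuzzyVocabulary, standard_vocabulary
from .rule_engine import SituationRule

__all__ = ["export_fcl"]

_DOMAIN_VARS = {
    "distance_m": "distance",
    "day_of_week": "day_of_week",
    "time_of_day": "time_of_day",
    "activity_level": "activity",
}


def export_fcl(
    rules: Iterable[SituationRule] = (),
    vocabulary: FuzzyVocabulary | None = None,
    block_name: str = "situation_engine",
) -> str:
    vocab = vocabulary or standard_vocabulary()
    lines = [f"FUNCTION_BLOCK {block_name}", "", "VAR_INPUT"]
    for var in dict.fromkeys(_DOMAIN_VARS.values()):
        lines.append(f"    {var} : REAL;")
    lines += ["END_VAR", "", "VAR_OUTPUT", "    situation : REAL;", "END_VAR", ""]

    by_var: dict[str, list] = {}
    for s in vocab.sets.values():
        by_var.setdefault(_DOMAIN_VARS[s.domain], []).append(s)
    for var, sets in by_var.items():
        lines.append(f"FUZZIFY {var}")
        for s in sets:
            pts = " ".join(f"({x:g}, {mu:g})" for x, mu in s.breakpoints)
            suffix = "  // cyclic" if s.cyclic else ""
            lines.append(f"    TERM {s.name} := {pts};{suffix}")
        lines.append("END_FUZZIFY")
        lines.append("")

    lines += ["RULEBLOCK situations", "    AND : PROD;", "    OR : MAX;"]
    for i, rule in enumerate(sorted(rules, key=lambda r: r.id), start=1):
        loc = f"distance IS {rule.location_term}"
        day = " OR ".join(f"day_of_week IS {t}" for t in sorted(rule.day_terms))
        tod = " OR ".join(f"time_of_day IS {t}" for t in sorted(rule.time_terms))
        lines.append(
            f"    // anchor ({rule.anchor.lat:.6f}, {rule.anchor.lon:.6f}); "
            f"activities: {', '.join(sorted(rule.activities))}"
        )
        lines.append(
            f"    RULE {i} : IF {loc} AND ({day}) AND ({tod}) AND activity IS on_activity "
            f"THEN situation IS {rule.id};"
        )
    lines += ["END_RULEBLOCK", "", "END_FUNCTION_BLOCK", ""]
    return "\n".join(lines)
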