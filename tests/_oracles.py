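"""Independent brute-force oracles used by several test modules.

These evaluate the printed piecewise branches of the night and weekend
sets directly, branch by branch, including the wrapped full-membership
regions — deliberately written without reusing any package code paths.
"""

from __future__ import annotations


def night_oracle(x: float) -> float:
    x = x % 24.0
    if 3.0 < x <= 19.0:
        return 0.0
    if 19.0 < x <= 21.0:
        return (x - 19.0) / 2.0
    if 1.0 < x <= 3.0:
        return (3.0 - x) / 2.0
    return 1.0  # wrapped plateau: x > 21 or x <= 1


def weekend_oracle(x: float) -> float:
    x = x % 7.0
    if 1.3 < x <= 5.7:
        return 0.0
    if 5.7 < x <= 6.3:
        return (x - 5.7) / 0.6
    if 0.7 < x <= 1.3:
        return (1.3 - x) / 0.6
    return 1.0  # wrapped plateau: x <= 0.7 or x > 6.3
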