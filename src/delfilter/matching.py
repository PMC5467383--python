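"""Interval match rules shared by merging, labeling and evaluation.

Two deletions called on the same chromosome are compared either by their
breakpoint offsets (the default, used both for de-duplicating candidates from
different callers and for deciding whether a candidate "is" a benchmark
deletion) or by reciprocal overlap, the common convention in SV benchmarking.
"""

from __future__ import annotations

from typing import Callable

# A match rule takes (a_start, a_end, b_start, b_end) in 0-based half-open
# coordinates on a shared chromosome and returns True if the two intervals
# describe the same deletion.
MatchRule = Callable[[int, int, int, int], bool]

DEFAULT_BREAKPOINT_FRACTION = 0.02
DEFAULT_RECIPROCAL_FRACTION = 0.5


def breakpoint_match(
    a_start: int,
    a_end: int,
    b_start: int,
    b_end: int,
    fraction: float = DEFAULT_BREAKPOINT_FRACTION,
) -> bool:
    """True when both breakpoints agree to within ``fraction`` of the
    shorter deletion's length.

    The distance between two deletions is taken as the larger of the two
    breakpoint offsets, so both edges must agree.  Symmetric in its
    arguments.
    """
    len_a = a_end - a_start
    len_b = b_end - b_start
    if len_a <= 0 or len_b <= 0:
        return False
    distance = max(abs(a_start - b_start), abs(a_end - b_end))
    return distance < fraction * min(len_a, len_b)


def reciprocal_overlap_match(
    a_start: int,
    a_end: int,
    b_start: int,
    b_end: int,
    fraction: float = DEFAULT_RECIPROCAL_FRACTION,
) -> bool:
    """True when the intervals overlap by at least ``fraction`` of each."""
    len_a = a_end - a_start
    len_b = b_end - b_start
    if len_a <= 0 or len_b <= 0:
        return False
    overlap = min(a_end, b_end) - max(a_start, b_start)
    return overlap >= fraction * len_a and overlap >= fraction * len_b


_RULES = {
    "breakpoint2pct": breakpoint_match,
    "reciprocal50": reciprocal_overlap_match,
}


def get_match_rule(rule: str | MatchRule) -> MatchRule:
    """Resolve a rule name (``breakpoint2pct`` or ``reciprocal50``) or pass a
    callable through unchanged."""
    if callable(rule):
        return rule
    try:
        return _RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown match rule {rule!r}; expected one of {sorted(_RULES)}"
        ) from None
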