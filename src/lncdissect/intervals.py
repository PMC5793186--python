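"""Interval arithmetic on exon chains and genomic spans.

All coordinates are 0-based half-open ``(start, end)`` with ``start < end``.
Exon chains are sorted, non-overlapping tuples of such intervals.
"""

from __future__ import annotations

from typing import Sequence

Interval = tuple[int, int]


def overlap_bp(a: Interval, b: Interval) -> int:
    """Length in bases of the intersection of two intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def spans_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def span_gap(a: Interval, b: Interval) -> int:
    """Closest-end distance between two spans; 0 when they overlap or abut."""
    if spans_overlap(a, b):
        return 0
    if a[1] <= b[0]:
        return b[0] - a[1]
    return a[0] - b[1]


def exonic_overlap_bp(exons_a: Sequence[Interval], exons_b: Sequence[Interval]) -> int:
    """Total overlapping bases between two sorted, non-overlapping exon chains.

    Linear merge-sweep; both chains must be sorted ascending.
    """
    i = j = 0
    total = 0
    while i < len(exons_a) and j < len(exons_b):
        total += overlap_bp(exons_a[i], exons_b[j])
        if exons_a[i][1] <= exons_b[j][1]:
            i += 1
        else:
            j += 1
    return total
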