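"""Half-open time-interval arithmetic shared across the pipeline.

All intervals are ``[start, end)`` with timezone-aware UTC ``datetime``
endpoints.  The same conventions are used for seizure events, detections
and non-collection (wear-mask) gaps, so the overlap/exclusion logic lives
in one place.
"""
from __future__ import annotations

from datetime import datetime, timedelta
from typing import Iterable, Sequence

Interval = tuple[datetime, datetime]


def validate_interval(start: datetime, end: datetime) -> None:
    if not start < end:
        raise ValueError(f"interval start must precede end: {start!r} >= {end!r}")


def intersects(a: Interval, b: Interval) -> bool:
    """True iff the half-open intervals overlap by a positive duration."""
    return max(a[0], b[0]) < min(a[1], b[1])


def overlap_seconds(a: Interval, b: Interval) -> float:
    """Length of the intersection in seconds (0 if disjoint)."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max((hi - lo).total_seconds(), 0.0)


def gap_seconds(a: Interval, b: Interval) -> float:
    """Shortest distance between two intervals in seconds (0 if they touch or overlap)."""
    if intersects(a, b):
        return 0.0
    if a[1] <= b[0]:
        return (b[0] - a[1]).total_seconds()
    return (a[1] - b[0]).total_seconds()


def within_tolerance(a: Interval, b: Interval, tolerance_s: float) -> bool:
    """True iff the intervals overlap or lie within ``tolerance_s`` of each other."""
    return gap_seconds(a, b) <= tolerance_s


def duration_seconds(iv: Interval) -> float:
    return (iv[1] - iv[0]).total_seconds()


def sort_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    return sorted(ivs, key=lambda iv: (iv[0], iv[1]))


def check_disjoint_sorted(ivs: Sequence[Interval]) -> None:
    """Raise if intervals are not sorted and pairwise disjoint."""
    for prev, cur in zip(ivs, ivs[1:]):
        if cur[0] < prev[1]:
            raise ValueError(f"intervals overlap or are unsorted: {prev!r} vs {cur!r}")


def clip_to(iv: Interval, extent: Interval) -> Interval | None:
    """Intersect ``iv`` with ``extent``; None if empty."""
    lo = max(iv[0], extent[0])
    hi = min(iv[1], extent[1])
    if lo >= hi:
        return None
    return (lo, hi)


def shift(iv: Interval, seconds: float) -> Interval:
    d = timedelta(seconds=seconds)
    return (iv[0] + d, iv[1] + d)
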