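"""Interval arithmetic on 1-based inclusive coordinates.

These are the primitives behind the consensus-overlap, segmental-duplication
coverage and maximum-stack operations; all take plain ``(start, end)`` tuples
with ``end >= start`` and count bases inclusively (``[1, 10]`` has 10 bases).
"""

from __future__ import annotations

from typing import Iterable, Sequence


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of shared bases between two inclusive intervals (0 if disjoint)."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, hi - lo + 1)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of inclusive intervals as a sorted list of disjoint intervals.

    Adjacent-but-not-overlapping intervals ([1,5], [6,9]) are NOT merged:
    union coverage must count bases, and base counting is unaffected either
    way, but downstream overlap tests require a shared base.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:  # shares >= 1 base
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def union_coverage(target: tuple[int, int], regions: Iterable[tuple[int, int]]) -> int:
    """Bases of ``target`` covered by the union of ``regions``."""
    covered = 0
    for s, e in merge_intervals(regions):
        covered += overlap_len(target, (s, e))
    return covered


def max_stack(
    intervals: Sequence[tuple[int, int]],
) -> tuple[tuple[int, int], int]:
    """Leftmost maximal-depth locus of a stack of inclusive intervals.

    Sweep-line over breakpoints; returns ``((start, end), depth)`` where the
    locus is the leftmost maximal run of positions attaining the maximum
    depth.  The caller is responsible for de-duplicating intervals that must
    count once (e.g. two calls from the same sample).
    """
    if not intervals:
        raise ValueError("max_stack of an empty interval set")
    # events at position p: +1 when an interval starts at p, -1 at end+1
    events: dict[int, int] = {}
    for s, e in intervals:
        events[s] = events.get(s, 0) + 1
        events[e + 1] = events.get(e + 1, 0) - 1
    positions = sorted(events)
    depth = 0
    best_depth = 0
    best_start = positions[0]
    best_end = positions[0]
    in_best = False
    for p in positions:
        depth += events[p]
        if depth > best_depth:
            best_depth = depth
            best_start = p
            in_best = True
        elif in_best and depth < best_depth:
            # first position where depth drops below the running maximum
            best_end = p - 1
            in_best = False
    return (best_start, best_end), best_depth
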