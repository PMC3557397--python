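"""CNV regions, maximum-stack carrier frequencies and the common/rare split.

A CNV region (CNVR) is a connected component of the call-overlap graph on one
chromosome: every member call overlaps some other member by at least one
base, transitively.  The region's carrier frequency is determined at the
locus with the maximum number of overlapping individual CNVs — a sample with
two calls stacked on one base still counts once — divided by the cohort
size.  Regions above 1% are the common stratum, at or below 1% rare.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, Sequence

from ._intervals import max_stack as _interval_max_stack
from ._intervals import merge_intervals
from .io import CnvCall

Direction = Literal["any", "del", "dup"]


def _direction_ok(call: CnvCall, direction: Direction) -> bool:
    if direction == "any":
        return True
    return call.is_deletion if direction == "del" else call.is_duplication


@dataclass
class CnvRegion:
    chrom: str
    start: int
    end: int
    member_calls: list[CnvCall]
    max_stack_count: int = 0
    max_stack_locus: tuple[int, int] | None = None
    frequency: float = 0.0
    stratum: str | None = None  # "common" | "rare"

    @property
    def n_samples(self) -> int:
        return len({c.sample_id for c in self.member_calls})


def merge_regions(calls: Sequence[CnvCall]) -> list[CnvRegion]:
    """Connected components of interval overlap, per chromosome.

    The region span is the union envelope of its member calls.  Output is
    sorted by (chrom, start) and invariant to input order.
    """
    by_chrom: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)
    regions: list[CnvRegion] = []
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.sample_id))
        current: list[CnvCall] = []
        cur_end = -1
        for c in chrom_calls:
            if current and c.start <= cur_end:  # shares >= 1 base with component
                current.append(c)
                cur_end = max(cur_end, c.end)
            else:
                if current:
                    regions.append(_close_region(chrom, current))
                current = [c]
                cur_end = c.end
        if current:
            regions.append(_close_region(chrom, current))
    return regions


def _close_region(chrom: str, members: list[CnvCall]) -> CnvRegion:
    return CnvRegion(
        chrom=chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        member_calls=list(members),
    )


def stack_max(region: CnvRegion) -> tuple[tuple[int, int], int]:
    """Leftmost maximal-depth locus of a region, depth in distinct samples.

    Calls from the same sample are merged first so a sample never contributes
    more than one unit of depth at any base.
    """
    if not region.member_calls:
        raise ValueError("stack_max of an empty region")
    per_sample: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for c in region.member_calls:
        per_sample[c.sample_id].append((c.start, c.end))
    intervals: list[tuple[int, int]] = []
    for ivs in per_sample.values():
        intervals.extend(merge_intervals(ivs))
    locus, depth = _interval_max_stack(intervals)
    return locus, depth


def classify_regions(
    regions: Sequence[CnvRegion], n_samples: int, threshold: float = 0.01
) -> list[CnvRegion]:
    """Fill max-stack locus/count, frequency and stratum on every region.

    A region is common iff its frequency strictly exceeds the threshold;
    exactly 1% is rare ("no more than 1% of the samples").
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    for r in regions:
        locus, depth = stack_max(r)
        r.max_stack_locus = locus
        r.max_stack_count = depth
        r.frequency = depth / n_samples
        r.stratum = "common" if r.frequency > threshold else "rare"
    return list(regions)


def classify_calls(
    regions: Sequence[CnvRegion], n_samples: int, threshold: float = 0.01
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Split member calls into (common, rare) strata; every call inherits its
    region's stratum, so the two lists partition the QC-passed call set."""
    classify_regions(regions, n_samples, threshold)
    common: list[CnvCall] = []
    rare: list[CnvCall] = []
    for r in regions:
        (common if r.stratum == "common" else rare).extend(r.member_calls)
    return common, rare


def stratify_calls(
    calls: Sequence[CnvCall],
    n_samples: int,
    threshold: float = 0.01,
    direction: Direction = "any",
) -> tuple[list[CnvRegion], list[CnvCall], list[CnvCall]]:
    """Build regions and split calls into common/rare in one step.

    ``direction`` restricts which calls are pooled when building regions and
    counting the stack (default pools deletions and duplications; per-
    direction frequencies are available as a switch).  Calls excluded by the
    direction filter are not returned in either stratum.
    """
    use = [c for c in calls if _direction_ok(c, direction)]
    regions = merge_regions(use)
    common, rare = classify_calls(regions, n_samples, threshold)
    return regions, common, rare
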