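"""Dual-caller consensus and quality-control cascade for CNV calls.

The cascade removes, in order:

1. primary-caller calls not confirmed by the secondary caller (same sample,
   same direction, at least 10% overlap of the primary call);
2. calls with LOD confidence <= 2, fewer than 5 markers, shorter than 4 kb,
   or longer than 1 Mb;
3. whole samples with an extreme CNV load (> 110 calls or > 7.5 Mb total
   length) or poor array quality (median copy-number variance > 2 or
   LRR SD > 0.4);
4. (rare stratum only) calls with > 50% of their bases inside segmental
   duplications, which are prone to artefactual calls.

All length thresholds are in bases on 1-based inclusive coordinates.  Call
boundaries of the primary caller are authoritative throughout: the secondary
caller only confirms, never reshapes, a call.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from ._intervals import overlap_len, union_coverage
from .io import CnvCall, ReferenceRegion, SampleRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcConfig:
    """Thresholds of the QC cascade; defaults are the published cascade."""

    min_overlap_fraction: float = 0.10
    min_confidence: float = 2.0  # strict: keep iff confidence > this
    min_markers: int = 5
    min_length: int = 4_000
    max_length: int = 1_000_000
    max_calls_per_sample: int = 110
    max_total_length_per_sample: int = 7_500_000
    max_median_cn_variance: float = 2.0
    max_lrr_sd: float = 0.4
    max_segdup_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.min_length < self.max_length:
            raise ValueError("min_length must be < max_length")


@dataclass
class QcReport:
    """Removal counts per filter, in application order."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, removed: int) -> None:
        self.steps.append((name, removed))

    def total_removed(self, prefix: str = "") -> int:
        return sum(n for name, n in self.steps if name.startswith(prefix))

    def as_rows(self) -> list[dict]:
        return [{"filter": name, "removed": n} for name, n in self.steps]


def overlap_fraction(a: CnvCall, b: CnvCall) -> float:
    """Fraction of call ``a`` covered by call ``b`` (asymmetric by design:
    the denominator is the length of ``a``).  Different chromosomes -> 0."""
    if a.chrom != b.chrom:
        return 0.0
    return overlap_len((a.start, a.end), (b.start, b.end)) / a.length


def consensus_calls(
    primary_calls: Sequence[CnvCall],
    secondary_calls: Sequence[CnvCall],
    cfg: QcConfig = QcConfig(),
) -> list[CnvCall]:
    """Keep a primary-caller call iff the same sample has a secondary-caller
    call of the same direction overlapping it by >= ``min_overlap_fraction``.

    Direction must agree (deletion with deletion, duplication with
    duplication): a 1-copy and a 3-copy call at one locus are contradictory
    evidence, not confirmation.  Kept calls retain primary-caller boundaries.
    """
    by_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for c in secondary_calls:
        by_sample[c.sample_id].append(c)
    primary_samples = {c.sample_id for c in primary_calls}
    only_secondary = set(by_sample) - primary_samples
    only_primary = primary_samples - set(by_sample)
    for missing in sorted(only_primary | only_secondary):
        log.warning("sample %s present in only one caller's output; dropped", missing)
    kept = []
    for call in primary_calls:
        if call.sample_id not in by_sample:
            continue
        for other in by_sample[call.sample_id]:
            if other.is_deletion != call.is_deletion:
                continue
            if overlap_fraction(call, other) >= cfg.min_overlap_fraction:
                kept.append(call)
                break
    return kept


def filter_call_quality(
    calls: Sequence[CnvCall], cfg: QcConfig = QcConfig()
) -> list[CnvCall]:
    """Keep iff confidence > 2, >= 5 markers, and length in [4 kb, 1 Mb].

    Boundary semantics follow the published wording literally: a LOD of
    exactly 2.0 is removed ("larger than two"), a call of exactly 4,000 bases
    or 5 markers is kept ("less than five markers or four kilobases"), and a
    call of exactly 1 Mb is kept ("longer than one megabase" removes it only
    beyond 1 Mb).
    """
    return [
        c
        for c in calls
        if c.confidence > cfg.min_confidence
        and c.n_markers >= cfg.min_markers
        and cfg.min_length <= c.length <= cfg.max_length
    ]


def recompute_sample_metrics(
    samples: Sequence[SampleRecord], calls: Sequence[CnvCall]
) -> list[SampleRecord]:
    """Refresh n_calls / total_cnv_length from the surviving calls; the array
    quality metrics (lrr_sd, median_cn_variance) are input metadata."""
    n: dict[str, int] = defaultdict(int)
    tot: dict[str, int] = defaultdict(int)
    for c in calls:
        n[c.sample_id] += 1
        tot[c.sample_id] += c.length
    return [
        SampleRecord(
            sample_id=s.sample_id,
            phenotype=s.phenotype,
            n_calls=n[s.sample_id],
            total_cnv_length=tot[s.sample_id],
            median_cn_variance=s.median_cn_variance,
            lrr_sd=s.lrr_sd,
        )
        for s in samples
    ]


def filter_samples(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    cfg: QcConfig = QcConfig(),
) -> tuple[list[SampleRecord], list[CnvCall], QcReport]:
    """Remove samples with extreme CNV load or poor array quality, and all
    their calls with them.  All four rules are strict inequalities, so a
    sample at exactly 110 calls or LRR SD exactly 0.4 is kept."""
    known = {s.sample_id for s in samples}
    for c in calls:
        if c.sample_id not in known:
            raise KeyError(f"no sample metrics for sample {c.sample_id!r}")
    samples = recompute_sample_metrics(samples, calls)
    report = QcReport()
    removed: dict[str, set[str]] = {
        "sample_n_calls": set(),
        "sample_total_length": set(),
        "sample_cn_variance_or_lrr_sd": set(),
    }
    for s in samples:
        if s.n_calls > cfg.max_calls_per_sample:
            removed["sample_n_calls"].add(s.sample_id)
        elif s.total_cnv_length > cfg.max_total_length_per_sample:
            removed["sample_total_length"].add(s.sample_id)
        elif (
            s.median_cn_variance > cfg.max_median_cn_variance
            or s.lrr_sd > cfg.max_lrr_sd
        ):
            removed["sample_cn_variance_or_lrr_sd"].add(s.sample_id)
    bad = set().union(*removed.values())
    for name in ("sample_n_calls", "sample_total_length", "sample_cn_variance_or_lrr_sd"):
        report.add(name, len(removed[name]))
    kept_samples = [s for s in samples if s.sample_id not in bad]
    kept_calls = [c for c in calls if c.sample_id not in bad]
    report.add("calls_of_removed_samples", len(calls) - len(kept_calls))
    return kept_samples, kept_calls, report


def segdup_fraction(call: CnvCall, segdups: Sequence[ReferenceRegion]) -> float:
    """Fraction of a call's bases inside the union of segmental duplications."""
    regions = [(r.start, r.end) for r in segdups if r.chrom == call.chrom]
    return union_coverage((call.start, call.end), regions) / call.length


def filter_segdup(
    rare_calls: Sequence[CnvCall],
    segdup_regions: Sequence[ReferenceRegion],
    cfg: QcConfig = QcConfig(),
) -> list[CnvCall]:
    """Remove a rare call iff > 50% of its bases fall in segmental
    duplications (union coverage; exactly 50% is kept)."""
    by_chrom: dict[str, list[ReferenceRegion]] = defaultdict(list)
    for r in segdup_regions:
        by_chrom[r.chrom].append(r)
    kept = []
    for c in rare_calls:
        regions = [(r.start, r.end) for r in by_chrom.get(c.chrom, ())]
        covered = union_coverage((c.start, c.end), regions)
        if covered / c.length <= cfg.max_segdup_fraction:
            kept.append(c)
    return kept


def run_call_qc(
    primary_calls: Sequence[CnvCall],
    secondary_calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    cfg: QcConfig = QcConfig(),
) -> tuple[list[SampleRecord], list[CnvCall], QcReport]:
    """Consensus + call-quality + sample filters (the segdup filter runs
    later, on the rare stratum only).  Returns surviving samples and calls
    plus a report whose removal counts sum to input minus output."""
    report = QcReport()
    consensus = consensus_calls(primary_calls, secondary_calls, cfg)
    report.add("not_in_both_callers", len(primary_calls) - len(consensus))
    quality = filter_call_quality(consensus, cfg)
    report.add("call_quality", len(consensus) - len(quality))
    kept_samples, kept_calls, sample_report = filter_samples(quality, samples, cfg)
    report.steps.extend(sample_report.steps)
    return kept_samples, kept_calls, report
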