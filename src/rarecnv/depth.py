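"""Copy-number estimation from targeted-sequencing read counts.

Copy number over a targeted region is proportional to the sequence depth
ratio: the region read count normalised by region length and by the sample's
total read count (scaled by 1e9 for readability).  A histogram of ratios
across a cohort separates into clusters corresponding to integer copy
numbers; a homozygous deletion yields exactly zero reads, so exact-zero
ratios are pre-assigned copy number 0 before clustering.

Clustering is exact, deterministic 1-D partitioning: the split of the sorted
nonzero ratios into k-1 contiguous groups minimising the within-cluster sum
of squares, found by dynamic programming (no random initialisation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

RATIO_SCALE = 1e9


@dataclass
class DepthRecord:
    sample_id: str
    region: str
    region_length: int
    region_reads: int
    total_reads: int
    ratio: float = 0.0
    copy_number: int | None = None


def depth_ratio(region_reads: int, region_length: int, total_reads: int) -> float:
    """(reads / region length) / total reads, scaled by 1e9."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive (sample-level failure)")
    if region_reads < 0:
        raise ValueError("region_reads must be >= 0")
    return region_reads / region_length / total_reads * RATIO_SCALE


def read_depth_counts(path: str | Path) -> list[DepthRecord]:
    """Read the per-region read-count table (TSV with header: sample_id,
    region, region_length, region_reads, total_reads)."""
    records = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    required = ("sample_id", "region", "region_length", "region_reads", "total_reads")
    idx = {}
    for col in required:
        if col not in header:
            raise ValueError(f"{path}: missing column {col!r}")
        idx[col] = header.index(col)
    for line in lines[1:]:
        parts = line.split("\t")
        rec = DepthRecord(
            sample_id=parts[idx["sample_id"]],
            region=parts[idx["region"]],
            region_length=int(parts[idx["region_length"]]),
            region_reads=int(parts[idx["region_reads"]]),
            total_reads=int(parts[idx["total_reads"]]),
        )
        rec.ratio = depth_ratio(rec.region_reads, rec.region_length, rec.total_reads)
        records.append(rec)
    return records


def _optimal_1d_partition(sorted_values: np.ndarray, k: int) -> list[np.ndarray]:
    """Split sorted values into k contiguous groups minimising within-group
    sum of squares (exact dynamic programming over split points)."""
    n = len(sorted_values)
    prefix = np.concatenate([[0.0], np.cumsum(sorted_values)])
    prefix2 = np.concatenate([[0.0], np.cumsum(sorted_values**2)])

    def sse(i: int, j: int) -> float:  # values[i:j]
        m = j - i
        s = prefix[j] - prefix[i]
        s2 = prefix2[j] - prefix2[i]
        return s2 - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            best, arg = np.inf, g - 1
            for i in range(g - 1, j):
                v = cost[g - 1, i] + sse(i, j)
                if v < best:
                    best, arg = v, i
            cost[g, j] = best
            back[g, j] = arg
    bounds = [n]
    j = n
    for g in range(k, 0, -1):
        j = back[g, j]
        bounds.append(j)
    bounds = bounds[::-1]
    return [np.arange(bounds[g], bounds[g + 1]) for g in range(k)]


def cluster_copy_number(
    ratios: Sequence[float],
    k: int = 3,
    anchor_index: int | None = None,
    anchor_copy_number: int = 2,
) -> np.ndarray:
    """Assign integer copy numbers to a cohort of depth ratios.

    Exact zeros are pre-assigned copy number 0 (no DNA present); the
    remaining ratios are clustered into k-1 contiguous groups by exact 1-D
    partitioning, and clusters are mapped to copy numbers in increasing ratio
    order — the zero group (when present) is 0, then 1, 2, ...

    That default anchoring can mislabel a cohort in which the lowest cluster
    is not actually the lowest copy number; ``anchor_index`` names a sample
    of known copy number (default 2) and shifts the labels of the nonzero
    clusters so the anchor lands on it.  Exact-zero samples always stay 0.
    """
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios < 0):
        raise ValueError("ratios must be >= 0")
    n = len(ratios)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    cn = np.zeros(n, dtype=int)
    nonzero = np.flatnonzero(ratios > 0)
    # copy number 0 is reserved for exact-zero ratios; the nonzero ratios
    # always form the remaining k-1 clusters, labelled upward from 1
    n_nonzero_clusters = k - 1
    values = ratios[nonzero]
    order = np.argsort(values, kind="stable")
    n_distinct = len(np.unique(values))
    if 0 < n_distinct < n_nonzero_clusters:
        log.warning(
            "only %d distinct nonzero ratios for %d clusters; collapsing",
            n_distinct,
            n_nonzero_clusters,
        )
        n_nonzero_clusters = n_distinct
    if len(nonzero):
        groups = _optimal_1d_partition(values[order], n_nonzero_clusters)
        for g, members in enumerate(groups):
            cn[nonzero[order[members]]] = 1 + g
    if anchor_index is not None:
        if ratios[anchor_index] == 0:
            raise ValueError("anchor sample has a zero ratio; cannot anchor")
        shift = anchor_copy_number - cn[anchor_index]
        mask = ratios > 0
        cn[mask] = cn[mask] + shift
        if np.any(cn < 0):
            raise ValueError("anchoring would produce negative copy numbers")
    return cn


def cluster_concordance(
    assignment_a: dict[str, int], assignment_b: dict[str, int]
) -> tuple[int, int]:
    """Number of shared samples placed in the same cluster by two
    assignments, after the label permutation of b that maximises agreement
    (cluster identity, not label value, is what is compared)."""
    shared = sorted(set(assignment_a) & set(assignment_b))
    if not shared:
        raise ValueError("assignments share no sample ids")
    a = np.array([assignment_a[s] for s in shared])
    b = np.array([assignment_b[s] for s in shared])
    b_labels = sorted(set(b.tolist()))
    a_labels = sorted(set(a.tolist()) | set(b_labels))
    best = 0
    for perm in itertools.permutations(a_labels, len(b_labels)):
        mapping = dict(zip(b_labels, perm))
        agree = int(np.sum(a == np.array([mapping[x] for x in b])))
        best = max(best, agree)
    return best, len(shared)
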