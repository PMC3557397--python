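"""Exact 2x2 inference, locus scans, gene-level carrier association and
global burden metrics, each with its permutation null.

The permutation scheme is the same everywhere: case/control labels are
shuffled over the fixed observed call-to-sample mapping.  Family-wise error
across a battery of tests is controlled by the min-p method — for every
permutation the minimal p-value over the battery is recorded, and a test's
empirical p is the fraction of permutations whose minimum is at least as
extreme as the test's observed p.  All empirical p-values use the
(1 + exceedances) / (n_perm + 1) estimator, which is conservative and never
zero.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .io import CnvCall, GeneModel, ReferenceRegion, SampleRecord
from .regions import Direction, _direction_ok, merge_regions

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# 2x2 machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CarrierTable:
    """Carrier counts: a/b = case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("carrier counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_carriers(self) -> int:
        return self.a + self.c

    @property
    def case_pct(self) -> float:
        return 100.0 * self.a / self.n_cases if self.n_cases else float("nan")

    @property
    def control_pct(self) -> float:
        return 100.0 * self.c / self.n_controls if self.n_controls else float("nan")

    @property
    def case_pct_combined(self) -> float:
        """Case carriers as a percentage of the COMBINED cohort — the
        denominator convention of the published association tables (both
        conventions are emitted in result output)."""
        return 100.0 * self.a / self.n_total if self.n_total else float("nan")

    @property
    def control_pct_combined(self) -> float:
        """Control carriers as a percentage of the combined cohort."""
        return 100.0 * self.c / self.n_total if self.n_total else float("nan")


@dataclass
class AssociationResult:
    target: str
    table: CarrierTable
    p_unadjusted: float
    p_empirical: float | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    dgv_false_positive: bool | None = None
    locus: tuple[str, int, int] | None = None


def fisher_exact(t: CarrierTable) -> float:
    """Exact two-sided Fisher p: the sum of hypergeometric probabilities of
    all tables with the observed margins whose point probability does not
    exceed the observed table's (within a 1e-7 relative tolerance).

    A table with a zero carrier margin carries no information; p = 1.
    """
    if t.n_carriers == 0 or t.a + t.c == t.n_total or t.n_cases == 0 or t.n_controls == 0:
        log.debug("degenerate 2x2 margin; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def fisher_p_lookup(n_carriers: int, n_cases: int, n_total: int) -> np.ndarray:
    """Vector of two-sided Fisher p-values indexed by the case-carrier count
    ``a`` (0..min(n_carriers, n_cases)) for fixed margins.

    Shares the point-probability definition of :func:`fisher_exact`; used to
    make label permutations cheap (the margins are permutation-invariant).
    """
    lo = max(0, n_carriers - (n_total - n_cases))
    hi = min(n_carriers, n_cases)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, n_carriers, n_cases)
    out = np.ones(hi + 1)
    for a in range(lo, hi + 1):
        out[a] = pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum()
    return np.minimum(out, 1.0)


def odds_ratio_cmle(
    t: CarrierTable, confidence: float = 0.95
) -> tuple[float | None, float | None, float | None]:
    """Conditional maximum-likelihood odds ratio with exact confidence
    interval (noncentral hypergeometric likelihood, Fisher framework).

    A zero cell on one side yields an infinite (or zero) estimate with a
    finite one-sided exact bound; a table with both carrier cells zero is
    undefined and reported as missing.
    """
    if t.a == 0 and t.c == 0:
        log.warning("odds ratio undefined: no carriers in either group")
        return None, None, None
    res = _scipy_odds_ratio([[t.a, t.b], [t.c, t.d]], kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), float(ci.low), float(ci.high)


# ---------------------------------------------------------------------------
# Permutation min-p FWER
# ---------------------------------------------------------------------------


def minp_permutation(
    test_battery: Callable[[np.ndarray], np.ndarray],
    phenotypes: np.ndarray,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Empirical family-wise p-values by the permutation min-p method.

    ``test_battery`` maps a boolean case-indicator vector to the battery's
    p-value vector and must be deterministic.  For each permutation the
    labels are shuffled, the battery recomputed, and its minimum recorded;
    ``p_empirical[i] = (1 + #{perm : min_p_perm <= p_obs[i]}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    phenotypes = np.asarray(phenotypes, dtype=bool)
    rng = np.random.default_rng(seed)
    p_obs = np.asarray(test_battery(phenotypes), dtype=float)
    mins = np.empty(n_perm)
    for i in range(n_perm):
        mins[i] = np.min(test_battery(rng.permutation(phenotypes)))
    exceed = (mins[None, :] <= p_obs[:, None]).sum(axis=1)
    return (1.0 + exceed) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# Carrier counting
# ---------------------------------------------------------------------------


def _overlapping_genes(
    call: CnvCall, genes_by_chrom: dict[str, list[GeneModel]]
) -> list[GeneModel]:
    return [
        g
        for g in genes_by_chrom.get(call.chrom, ())
        if g.start <= call.end and g.end >= call.start
    ]


def _genes_by_chrom(genes: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    by: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by[g.chrom].append(g)
    return by


def carrier_matrix(
    calls: Sequence[CnvCall],
    genes: Sequence[GeneModel],
    samples: Sequence[SampleRecord],
    direction: Direction = "any",
) -> tuple[np.ndarray, list[str]]:
    """Boolean (n_samples x n_genes) matrix: sample carries >= 1 qualifying
    call overlapping the gene by >= 1 base.  Column order follows ``genes``;
    row order follows ``samples``."""
    sample_idx = {s.sample_id: i for i, s in enumerate(samples)}
    gene_idx = {g.symbol: j for j, g in enumerate(genes)}
    by_chrom = _genes_by_chrom(genes)
    m = np.zeros((len(samples), len(genes)), dtype=bool)
    for call in calls:
        if not _direction_ok(call, direction):
            continue
        i = sample_idx.get(call.sample_id)
        if i is None:
            continue
        for g in _overlapping_genes(call, by_chrom):
            m[i, gene_idx[g.symbol]] = True
    return m, [g.symbol for g in genes]


def _case_mask(samples: Sequence[SampleRecord]) -> np.ndarray:
    return np.array([s.is_case for s in samples], dtype=bool)


def gene_carrier_counts(
    rare_calls: Sequence[CnvCall],
    genes: Sequence[GeneModel],
    samples: Sequence[SampleRecord],
    direction: Direction = "any",
) -> dict[str, CarrierTable]:
    """Per-gene 2x2 carrier tables: a sample counts once per gene no matter
    how many of its rare calls overlap it."""
    m, symbols = carrier_matrix(rare_calls, genes, samples, direction)
    cases = _case_mask(samples)
    n_cases = int(cases.sum())
    n_controls = len(samples) - n_cases
    a = m[cases].sum(axis=0)
    c = m[~cases].sum(axis=0)
    return {
        sym: CarrierTable(int(a[j]), n_cases - int(a[j]), int(c[j]), n_controls - int(c[j]))
        for j, sym in enumerate(symbols)
    }


def _battery_from_matrix(m: np.ndarray, n_total: int) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized battery: per-column Fisher p under a case-indicator vector,
    via precomputed p-lookups keyed on each column's fixed carrier margin."""
    carriers = m.sum(axis=0).astype(int)
    mf = m.astype(np.float64)
    cache: dict[tuple[int, int], np.ndarray] = {}

    def battery(case_mask: np.ndarray) -> np.ndarray:
        n_cases = int(case_mask.sum())
        a = case_mask.astype(np.float64) @ mf  # case carriers per column
        p = np.empty(m.shape[1])
        for j in range(m.shape[1]):
            key = (int(carriers[j]), n_cases)
            if key not in cache:
                cache[key] = fisher_p_lookup(key[0], n_cases, n_total)
            p[j] = cache[key][int(a[j])]
        return p

    return battery


def gene_association(
    rare_calls: Sequence[CnvCall],
    genes: Sequence[GeneModel],
    samples: Sequence[SampleRecord],
    n_perm: int = 1000,
    seed: int = 0,
    direction: Direction = "any",
) -> list[AssociationResult]:
    """Per-gene Fisher tests with min-p permutation FWER correction.

    Genes with zero carriers in the whole cohort are skipped (they can never
    reject and would only dilute nothing — the min-p battery is unaffected by
    constant-1 members).
    """
    m, symbols = carrier_matrix(rare_calls, genes, samples, direction)
    keep = m.any(axis=0)
    m = m[:, keep]
    symbols = [s for s, k in zip(symbols, keep) if k]
    if not symbols:
        return []
    cases = _case_mask(samples)
    battery = _battery_from_matrix(m, len(samples))
    p_obs = battery(cases)
    p_emp = minp_permutation(battery, cases, n_perm, seed)
    n_cases = int(cases.sum())
    n_controls = len(samples) - n_cases
    results = []
    for j, sym in enumerate(symbols):
        a = int(m[cases, j].sum())
        c = int(m[~cases, j].sum())
        t = CarrierTable(a, n_cases - a, c, n_controls - c)
        est, lo, hi = odds_ratio_cmle(t)
        results.append(
            AssociationResult(
                target=sym,
                table=t,
                p_unadjusted=float(p_obs[j]),
                p_empirical=float(p_emp[j]),
                odds_ratio=est,
                ci_low=lo,
                ci_high=hi,
            )
        )
    results.sort(key=lambda r: r.p_unadjusted)
    return results


def dgv_flag(
    results: Sequence[AssociationResult],
    known_cnv_regions: Sequence[ReferenceRegion],
    genes: Sequence[GeneModel],
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Flag significant genes whose case carrier frequency does not exceed
    the frequency of known CNVs already reported over the gene — the
    published rule for declaring a hit a likely false positive.

    A reference without frequencies disables flagging with a warning.
    """
    gene_by_symbol = {g.symbol: g for g in genes}
    have_freq = [r for r in known_cnv_regions if r.frequency is not None]
    if known_cnv_regions and not have_freq:
        log.warning("known-CNV reference lacks a frequency column; no flags set")
    by_chrom: dict[str, list[ReferenceRegion]] = defaultdict(list)
    for r in have_freq:
        by_chrom[r.chrom].append(r)
    for res in results:
        res.dgv_false_positive = False
        if res.p_empirical is not None and res.p_empirical >= alpha:
            continue
        gene = gene_by_symbol.get(res.target)
        if gene is None:
            continue
        case_freq = res.table.a / res.table.n_cases if res.table.n_cases else 0.0
        for ref in by_chrom.get(gene.chrom, ()):
            if ref.start <= gene.end and ref.end >= gene.start and ref.frequency >= case_freq:
                res.dgv_false_positive = True
                break
    return list(results)


# ---------------------------------------------------------------------------
# Locus scan (common stratum)
# ---------------------------------------------------------------------------


def locus_scan(
    common_calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    direction: Direction = "any",
) -> tuple[list[AssociationResult], np.ndarray]:
    """Fisher tests at the breakpoint-bounded loci of the common stratum.

    Test loci are the atomic intervals delimited by member-call breakpoints
    within each CNV region; at each locus a sample is a carrier iff it has
    >= 1 overlapping call of the requested direction.  Consecutive loci with
    identical carrier sets collapse to a single test, and an outermost locus
    of a region is excluded when its carrier set is a proper subset of its
    inner neighbour's — the signature of pure boundary truncation.

    Returns the per-locus results plus the carrier matrix backing them (for
    the permutation battery).
    """
    use = [c for c in common_calls if _direction_ok(c, direction)]
    sample_idx = {s.sample_id: i for i, s in enumerate(samples)}
    cases = _case_mask(samples)
    n_cases = int(cases.sum())
    n_controls = len(samples) - n_cases
    loci: list[tuple[str, int, int, frozenset[int]]] = []
    for region in merge_regions(use):
        points = sorted(
            {c.start for c in region.member_calls}
            | {c.end + 1 for c in region.member_calls}
        )
        atoms = []
        for lo, hi in zip(points[:-1], points[1:]):
            carr = frozenset(
                sample_idx[c.sample_id]
                for c in region.member_calls
                if c.start <= lo and c.end >= hi - 1 and c.sample_id in sample_idx
            )
            if carr:
                atoms.append((lo, hi - 1, carr))
        # collapse consecutive atoms with identical carrier sets
        collapsed: list[tuple[int, int, frozenset[int]]] = []
        for lo, hi, carr in atoms:
            if collapsed and collapsed[-1][2] == carr and collapsed[-1][1] + 1 == lo:
                collapsed[-1] = (collapsed[-1][0], hi, carr)
            else:
                collapsed.append((lo, hi, carr))
        # drop boundary-truncation edges
        if len(collapsed) >= 2 and collapsed[0][2] < collapsed[1][2]:
            collapsed = collapsed[1:]
        if len(collapsed) >= 2 and collapsed[-1][2] < collapsed[-2][2]:
            collapsed = collapsed[:-1]
        for lo, hi, carr in collapsed:
            loci.append((region.chrom, lo, hi, carr))
    if not loci:
        return [], np.zeros((len(samples), 0), dtype=bool)
    m = np.zeros((len(samples), len(loci)), dtype=bool)
    results = []
    for j, (chrom, lo, hi, carr) in enumerate(loci):
        m[list(carr), j] = True
        a = int(cases[list(carr)].sum())
        c = len(carr) - a
        t = CarrierTable(a, n_cases - a, c, n_controls - c)
        results.append(
            AssociationResult(
                target=f"{chrom}:{lo}-{hi}",
                table=t,
                p_unadjusted=fisher_exact(t),
                locus=(chrom, lo, hi),
            )
        )
    return results, m


def locus_association(
    common_calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    n_perm: int = 1000,
    seed: int = 0,
    direction: Direction = "any",
) -> list[AssociationResult]:
    """Locus scan with min-p permutation FWER over the whole battery."""
    results, m = locus_scan(common_calls, samples, direction)
    if not results:
        return []
    cases = _case_mask(samples)
    battery = _battery_from_matrix(m, len(samples))
    p_emp = minp_permutation(battery, cases, n_perm, seed)
    for res, pe in zip(results, p_emp):
        res.p_empirical = float(pe)
        est, lo, hi = odds_ratio_cmle(res.table)
        res.odds_ratio, res.ci_low, res.ci_high = est, lo, hi
    results.sort(key=lambda r: r.p_unadjusted)
    return results


# ---------------------------------------------------------------------------
# Global burden
# ---------------------------------------------------------------------------

BURDEN_METRICS = ("rate", "gene_rate", "mean_length", "total_length")
TYPE_STRATA = ("all", "dup_only", "del_only")


@dataclass
class BurdenResult:
    metric: str
    type_stratum: str
    case_mean: float
    control_mean: float
    ratio: float
    p: float | None = None


def burden_metrics(
    rare_calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneModel],
) -> tuple[dict[tuple[str, str], np.ndarray], list[BurdenResult]]:
    """Per-sample burden metrics for all (metric, type-stratum) pairs.

    rate = calls/sample; gene_rate = distinct genes hit/sample; mean_length
    and total_length in bases.  Zero-call samples contribute 0 to rate,
    gene_rate and total_length but are excluded (NaN) from mean_length —
    the mean of an empty set is undefined, and including zeros would make
    the published "mean length" uninterpretable.
    """
    if not samples:
        raise ValueError("empty cohort")
    idx = {s.sample_id: i for i, s in enumerate(samples)}
    by_chrom = _genes_by_chrom(genes)
    n = len(samples)
    table: dict[tuple[str, str], np.ndarray] = {}
    for stratum in TYPE_STRATA:
        direction: Direction = {"all": "any", "dup_only": "dup", "del_only": "del"}[stratum]
        counts = np.zeros(n)
        total_len = np.zeros(n)
        genes_hit: list[set[str]] = [set() for _ in range(n)]
        for c in rare_calls:
            if not _direction_ok(c, direction) or c.sample_id not in idx:
                continue
            i = idx[c.sample_id]
            counts[i] += 1
            total_len[i] += c.length
            for g in _overlapping_genes(c, by_chrom):
                genes_hit[i].add(g.symbol)
        mean_len = np.where(counts > 0, total_len / np.maximum(counts, 1), np.nan)
        table[("rate", stratum)] = counts
        table[("gene_rate", stratum)] = np.array([len(s) for s in genes_hit], dtype=float)
        table[("mean_length", stratum)] = mean_len
        table[("total_length", stratum)] = total_len
    cases = _case_mask(samples)
    results = []
    for (metric, stratum), x in table.items():
        case_mean = float(np.nanmean(x[cases])) if np.any(~np.isnan(x[cases])) else float("nan")
        control_mean = (
            float(np.nanmean(x[~cases])) if np.any(~np.isnan(x[~cases])) else float("nan")
        )
        ratio = case_mean / control_mean if control_mean > 0 else float("nan")
        results.append(BurdenResult(metric, stratum, case_mean, control_mean, ratio))
    return table, results


def burden_permutation(
    metric_table: dict[tuple[str, str], np.ndarray],
    samples: Sequence[SampleRecord],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """One-sided permutation p per (metric, stratum): the probability, under
    shuffled case/control labels, of a case:control ratio at least as large
    as observed; (1 + exceedances) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    cases = _case_mask(samples)
    n = len(samples)
    n_cases = int(cases.sum())
    keys = list(metric_table)
    X = np.column_stack([metric_table[k] for k in keys])
    finite = ~np.isnan(X)
    Xf = np.nan_to_num(X)
    # observed ratios
    obs_ratio = _ratios(cases, Xf, finite)
    perm_masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perm_masks[i, rng.choice(n, size=n_cases, replace=False)] = True
    pm = perm_masks.astype(np.float64)
    case_sum = pm @ Xf
    case_n = pm @ finite.astype(np.float64)
    ctrl_sum = Xf.sum(axis=0) - case_sum
    ctrl_n = finite.sum(axis=0) - case_n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (case_sum / case_n) / (ctrl_sum / ctrl_n)
    out = {}
    for j, key in enumerate(keys):
        if math.isnan(obs_ratio[j]):
            out[key] = float("nan")
            continue
        exceed = int(np.sum(ratios[:, j] >= obs_ratio[j]))
        out[key] = (1.0 + exceed) / (n_perm + 1.0)
    return out


def _ratios(case_mask: np.ndarray, Xf: np.ndarray, finite: np.ndarray) -> np.ndarray:
    cs = case_mask.astype(float) @ Xf
    cn = case_mask.astype(float) @ finite.astype(float)
    ts = Xf.sum(axis=0) - cs
    tn = finite.sum(axis=0) - cn
    with np.errstate(divide="ignore", invalid="ignore"):
        return (cs / cn) / (ts / tn)


def burden_analysis(
    rare_calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    genes: Sequence[GeneModel],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[BurdenResult]:
    """Burden metrics plus their one-sided permutation p-values."""
    table, results = burden_metrics(rare_calls, samples, genes)
    pvals = burden_permutation(table, samples, n_perm, seed)
    for r in results:
        r.p = pvals[(r.metric, r.type_stratum)]
    return results
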