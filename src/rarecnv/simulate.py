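"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a post-QC CNV case–control cohort: per-sample call
counts are Poisson (defaults 4.8 calls/control and 5.17 calls/case — the
published baseline burden rates), call positions are uniform over a
surrogate genome, lengths are log-normal truncated to the QC window
[4 kb, 1 Mb] with parameters chosen so the truncated mean is ~77 kb (the
published mean length), and ~60% of calls are deletions (the published
deletion:duplication rate split, 2.9 : 1.9).  A second caller's view of the
same genomes is derived from the primary calls by boundary jitter, random
false-negative drops and Poisson false-positive additions, so the consensus
filter has realistic work to do.

Risk effects are planted as *additional* carrier calls at a designated gene
(or across a gene set) with stated case/control penetrances, never as rate
shifts, so true carrier status is unambiguous for recovery scoring; every
planted carrier is recorded in a truth table.

What the generator does not emulate: marker-level intensity noise, genomic
clustering of CNV hotspots, linkage between nearby variants, and
population-genetic realism (recombination, allele-frequency spectra).  Green
tests on these cohorts establish that the statistical machinery is correct,
not that the biology of any particular genome is captured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    PRIMARY_CALLER,
    SECONDARY_CALLER,
    CnvCall,
    GeneModel,
    GeneSet,
    ReferenceRegion,
    SampleRecord,
    write_bed_regions,
    write_cnv_calls,
    write_gene_models,
    write_gene_sets,
    write_sample_table,
)

DEFAULT_GENOME = tuple((f"chr{i}", 120_000_000) for i in range(1, 23))


@dataclass
class SimConfig:
    n_cases: int = 189
    n_controls: int = 380
    cnv_rate_control: float = 4.8
    cnv_rate_case: float = 5.17
    deletion_fraction: float = 0.60
    # log-normal length parameters; truncated-to-[4kb, 1Mb] mean ~= 77 kb
    length_log_mean: float = 10.57
    length_log_sd: float = 1.2
    min_length: int = 4_000
    max_length: int = 1_000_000
    genome: tuple = DEFAULT_GENOME
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (10_000, 100_000)
    n_sets: int = 50
    set_size_range: tuple[int, int] = (5, 50)
    n_segdups: int = 0
    segdup_length: int = 50_000
    planted_gene: tuple[str, float, float] | None = None  # (symbol, case_pen, ctrl_pen)
    planted_set: tuple[str, float] | None = None  # (set_id, per-gene case excess rate)
    caller2_boundary_jitter_sd: float = 500.0
    caller2_fp_rate: float = 0.05
    caller2_fn_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cnv_rate_case < 0 or self.cnv_rate_control < 0:
            raise ValueError("CNV rates must be >= 0")
        if not 0 <= self.deletion_fraction <= 1:
            raise ValueError("deletion_fraction must be in [0, 1]")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("genome lengths must be positive")


@dataclass
class SimulatedCohort:
    samples: list[SampleRecord]
    primary_calls: list[CnvCall]
    secondary_calls: list[CnvCall]
    genes: list[GeneModel]
    sets: list[GeneSet]
    segdups: list[ReferenceRegion]
    truth: pd.DataFrame  # columns: sample_id, target, kind


def _draw_length(rng: np.random.Generator, cfg: SimConfig, size: int) -> np.ndarray:
    out = np.empty(size, dtype=int)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, size=int(need.sum()))
        ok = (draw >= cfg.min_length) & (draw <= cfg.max_length)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok].astype(int)
        need[idx] = False
    return out


def _place_calls(
    rng: np.random.Generator,
    cfg: SimConfig,
    sample_id: str,
    n_calls: int,
) -> list[CnvCall]:
    if n_calls == 0:
        return []
    chrom_lengths = np.array([l for _, l in cfg.genome], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()
    chrom_idx = rng.choice(len(cfg.genome), size=n_calls, p=chrom_p)
    lengths = _draw_length(rng, cfg, n_calls)
    is_del = rng.random(n_calls) < cfg.deletion_fraction
    calls = []
    for j in range(n_calls):
        chrom, clen = cfg.genome[chrom_idx[j]]
        length = min(int(lengths[j]), clen)
        start = int(rng.integers(1, clen - length + 2))
        # markers roughly every 1.5 kb, confidence a LOD-like positive score
        n_markers = max(5, int(length / 1500 + rng.integers(0, 5)))
        confidence = float(2.0 + rng.gamma(2.0, 5.0))
        calls.append(
            CnvCall(
                sample_id=sample_id,
                chrom=chrom,
                start=start,
                end=start + length - 1,
                copy_number=1 if is_del[j] else 3,
                n_markers=n_markers,
                confidence=confidence,
                caller=PRIMARY_CALLER,
            )
        )
    return calls


def _make_genes(rng: np.random.Generator, cfg: SimConfig) -> list[GeneModel]:
    genes = []
    chrom_lengths = np.array([l for _, l in cfg.genome], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()
    for i in range(cfg.n_genes):
        chrom, clen = cfg.genome[int(rng.choice(len(cfg.genome), p=chrom_p))]
        length = int(rng.integers(*cfg.gene_length_range))
        start = int(rng.integers(1, clen - length + 2))
        genes.append(
            GeneModel(symbol=f"GENE{i + 1:04d}", chrom=chrom, start=start, end=start + length - 1)
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _make_sets(
    rng: np.random.Generator, cfg: SimConfig, genes: list[GeneModel]
) -> list[GeneSet]:
    symbols = [g.symbol for g in genes]
    sets = []
    for i in range(cfg.n_sets):
        size = int(rng.integers(cfg.set_size_range[0], cfg.set_size_range[1] + 1))
        size = min(size, len(symbols))
        members = rng.choice(symbols, size=size, replace=False)
        sets.append(
            GeneSet(
                set_id=f"SET{i + 1:04d}",
                name=f"synthetic set {i + 1}",
                genes=frozenset(members.tolist()),
            )
        )
    return sets


def _planted_call(
    rng: np.random.Generator, sample_id: str, gene: GeneModel
) -> CnvCall:
    pad = int(rng.integers(500, 5_000))
    start = max(1, gene.start - pad)
    length = max(gene.end + pad - start + 1, 4_000)
    return CnvCall(
        sample_id=sample_id,
        chrom=gene.chrom,
        start=start,
        end=start + length - 1,
        copy_number=1,
        n_markers=max(5, length // 1500),
        confidence=float(5.0 + rng.gamma(2.0, 5.0)),
        caller=PRIMARY_CALLER,
    )


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort (samples, dual-caller call tables,
    gene models, gene sets, segdup annotation, truth table).

    One master seed derives independent per-stream generators (cohort
    structure, background calls, planted effects, secondary-caller noise) by
    fixed spawn order, so e.g. changing the caller-noise settings does not
    change the background calls.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_calls, rng_plant, rng_caller2 = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    genes = _make_genes(rng_struct, cfg)
    sets = _make_sets(rng_struct, cfg, genes)
    gene_by_symbol = {g.symbol: g for g in genes}

    segdups = []
    if cfg.n_segdups:
        chrom_lengths = np.array([l for _, l in cfg.genome], dtype=float)
        chrom_p = chrom_lengths / chrom_lengths.sum()
        for _ in range(cfg.n_segdups):
            chrom, clen = cfg.genome[int(rng_struct.choice(len(cfg.genome), p=chrom_p))]
            start = int(rng_struct.integers(1, clen - cfg.segdup_length + 2))
            segdups.append(
                ReferenceRegion(chrom=chrom, start=start, end=start + cfg.segdup_length - 1)
            )

    sample_ids = [f"CASE{i + 1:04d}" for i in range(cfg.n_cases)] + [
        f"CTRL{i + 1:04d}" for i in range(cfg.n_controls)
    ]
    phenotypes = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls

    primary: list[CnvCall] = []
    truth_rows: list[dict] = []
    for sid, phen in zip(sample_ids, phenotypes):
        rate = cfg.cnv_rate_case if phen == "case" else cfg.cnv_rate_control
        n_calls = int(rng_calls.poisson(rate))
        primary.extend(_place_calls(rng_calls, cfg, sid, n_calls))

    if cfg.planted_gene is not None:
        symbol, case_pen, ctrl_pen = cfg.planted_gene
        if symbol not in gene_by_symbol:
            raise ValueError(f"planted gene {symbol!r} absent from annotation")
        for sid, phen in zip(sample_ids, phenotypes):
            pen = case_pen if phen == "case" else ctrl_pen
            if rng_plant.random() < pen:
                primary.append(_planted_call(rng_plant, sid, gene_by_symbol[symbol]))
                truth_rows.append({"sample_id": sid, "target": symbol, "kind": "gene"})

    if cfg.planted_set is not None:
        set_id, excess = cfg.planted_set
        target_set = next((s for s in sets if s.set_id == set_id), None)
        if target_set is None:
            raise ValueError(f"planted set {set_id!r} absent from annotation")
        for sid, phen in zip(sample_ids, phenotypes):
            if phen != "case":
                continue
            for symbol in sorted(target_set.genes):
                if rng_plant.random() < excess:
                    primary.append(_planted_call(rng_plant, sid, gene_by_symbol[symbol]))
                    truth_rows.append({"sample_id": sid, "target": set_id, "kind": "set"})

    primary.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))

    # secondary caller: FN drops, boundary jitter, FP additions
    secondary: list[CnvCall] = []
    for c in primary:
        if rng_caller2.random() < cfg.caller2_fn_rate:
            continue
        js = int(rng_caller2.normal(0, cfg.caller2_boundary_jitter_sd)) if cfg.caller2_boundary_jitter_sd else 0
        je = int(rng_caller2.normal(0, cfg.caller2_boundary_jitter_sd)) if cfg.caller2_boundary_jitter_sd else 0
        start = max(1, c.start + js)
        end = max(start, c.end + je)
        secondary.append(
            CnvCall(
                sample_id=c.sample_id,
                chrom=c.chrom,
                start=start,
                end=end,
                copy_number=c.copy_number,
                n_markers=c.n_markers,
                confidence=c.confidence,
                caller=SECONDARY_CALLER,
            )
        )
    n_fp = int(rng_caller2.poisson(cfg.caller2_fp_rate * max(1, len(primary))))
    for _ in range(n_fp):
        sid = sample_ids[int(rng_caller2.integers(0, len(sample_ids)))]
        fp = _place_calls(rng_caller2, cfg, sid, 1)[0]
        secondary.append(
            CnvCall(
                sample_id=fp.sample_id,
                chrom=fp.chrom,
                start=fp.start,
                end=fp.end,
                copy_number=fp.copy_number,
                n_markers=fp.n_markers,
                confidence=fp.confidence,
                caller=SECONDARY_CALLER,
            )
        )
    secondary.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))

    n_per_sample: dict[str, int] = {sid: 0 for sid in sample_ids}
    len_per_sample: dict[str, int] = {sid: 0 for sid in sample_ids}
    for c in primary:
        n_per_sample[c.sample_id] += 1
        len_per_sample[c.sample_id] += c.length
    samples = [
        SampleRecord(
            sample_id=sid,
            phenotype=phen,
            n_calls=n_per_sample[sid],
            total_cnv_length=len_per_sample[sid],
            median_cn_variance=float(rng_struct.uniform(0.2, 1.2)),
            lrr_sd=float(rng_struct.uniform(0.1, 0.3)),
        )
        for sid, phen in zip(sample_ids, phenotypes)
    ]
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "target", "kind"])
    return SimulatedCohort(
        samples=samples,
        primary_calls=primary,
        secondary_calls=secondary,
        genes=genes,
        sets=sets,
        segdups=segdups,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort artifact as the text formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.tsv",
        "primary_calls": outdir / "calls_primary.tsv",
        "secondary_calls": outdir / "calls_secondary.tsv",
        "genes": outdir / "genes.bed",
        "sets": outdir / "sets.gmt",
        "segdups": outdir / "segdups.bed",
        "truth": outdir / "truth.tsv",
    }
    write_sample_table(cohort.samples, paths["samples"])
    write_cnv_calls(cohort.primary_calls, paths["primary_calls"])
    write_cnv_calls(cohort.secondary_calls, paths["secondary_calls"])
    write_gene_models(cohort.genes, paths["genes"])
    write_gene_sets(cohort.sets, paths["sets"])
    write_bed_regions(cohort.segdups, paths["segdups"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Depth-count tables
# ---------------------------------------------------------------------------


def simulate_depth_counts(
    n_samples: int = 62,
    proportions: Sequence[float] = (0.52, 0.40, 0.08),
    centers: Sequence[float] = (0.0, 0.5, 1.0),
    noise_sd: float = 0.0,
    total_reads: int = 125_000_000,
    region_length: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-region read-count table for a cohort with planted copy-number
    classes.

    Class sizes are the largest-remainder rounding of proportions x
    n_samples (default 52/40/8% of 62 -> 32/25/5).  Copy-number-0 samples
    get exactly 0 region reads; other classes draw Poisson counts around
    center x region_length x total_reads / 1e9, with optional multiplicative
    log-normal noise of scale ``noise_sd``.  The default coverage gives a
    heterozygous-deletion class ~Poisson(625) reads, i.e. a depth-ratio
    standard deviation of ~0.02 around the 0.5 center — cleanly separated
    clusters, as in a deep targeted-capture experiment.  Returns the counts
    table and the true class index per sample.
    """
    proportions = np.asarray(proportions, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not np.isclose(proportions.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    if len(proportions) != len(centers):
        raise ValueError("proportions and centers must have equal length")
    # largest-remainder apportionment of class sizes
    raw = proportions * n_samples
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    for i in np.argsort(-remainder)[: n_samples - sizes.sum()]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    rows = []
    true_class = []
    k = 0
    for cls, (size, center) in enumerate(zip(sizes, centers)):
        for _ in range(size):
            k += 1
            if center == 0:
                reads = 0
            else:
                lam = center * region_length * total_reads / 1e9
                if noise_sd > 0:
                    lam *= float(rng.lognormal(0.0, noise_sd))
                reads = int(rng.poisson(lam))
            rows.append(
                {
                    "sample_id": f"S{k:04d}",
                    "region": "target",
                    "region_length": region_length,
                    "region_reads": reads,
                    "total_reads": total_reads,
                }
            )
            true_class.append(cls)
    df = pd.DataFrame(rows)
    return df, np.array(true_class)


def simulate_set_carriers(
    n_cases: int = 189,
    n_controls: int = 380,
    n_null_sets: int = 200,
    null_rate_range: tuple[float, float] = (0.005, 0.05),
    planted_case_carriers: float = 10.0,
    planted_control_carriers: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Carrier-indicator matrix for gene-set calibration studies.

    Null sets share one carrier probability between cases and controls
    (drawn per set from ``null_rate_range``); one planted set has expected
    case/control carrier counts as given (defaults ~10 vs ~2 at 189/380,
    an odds ratio near 4).  Returns (carrier matrix samples x sets,
    case mask, planted column index).
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    cases = np.zeros(n, dtype=bool)
    cases[:n_cases] = True
    q = rng.uniform(*null_rate_range, size=n_null_sets)
    m = rng.random((n, n_null_sets)) < q[None, :]
    planted = np.zeros((n, 1), dtype=bool)
    planted[:n_cases, 0] = rng.random(n_cases) < planted_case_carriers / n_cases
    planted[n_cases:, 0] = rng.random(n_controls) < planted_control_carriers / n_controls
    matrix = np.concatenate([m, planted], axis=1)
    return matrix, cases, n_null_sets
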