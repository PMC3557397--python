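"""Pipeline orchestration: qc -> stratify -> associations -> report.

One YAML config drives a full run.  Every output table carries a header
comment naming the input checksums, the seed and the permutation count, and
a JSON provenance manifest in the run directory is sufficient to reproduce
every number: deterministic stages reproduce identical bytes, seeded
stochastic stages identical values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .association import (
    AssociationResult,
    burden_analysis,
    dgv_flag,
    gene_association,
    locus_association,
)
from .io import (
    read_bed_regions,
    read_cnv_calls,
    read_gene_models,
    read_gene_sets,
    read_sample_table,
    write_results,
)
from .pathways import pathway_association
from .qc import QcConfig, filter_segdup, run_call_qc
from .regions import stratify_calls

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    primary_calls: str
    secondary_calls: str
    samples: str
    genes: str
    sets: str | None = None
    segdups: str | None = None
    known_cnv: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    frequency_threshold: float = 0.01
    min_set_genes: int = 5
    max_set_genes: int = 700
    fdr_threshold: float = 0.05
    n_perm_locus: int = 1000
    n_perm_gene: int = 1000
    n_perm_burden: int = 10000
    n_perm_pathway: int = 1000
    seed: int = 0
    direction: str = "any"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QcConfig(**raw.pop("qc", {}))
        return cls(qc=qc, **raw)

    def validate(self) -> None:
        for name in ("primary_calls", "secondary_calls", "samples", "genes", "sets", "segdups", "known_cnv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {name}: {p} does not exist")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage in cascade order and write per-stage TSVs plus a
    provenance manifest.  Any stage failure aborts with the stage name."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {},
        "stages": {},
    }
    for name in ("primary_calls", "secondary_calls", "samples", "genes", "sets", "segdups", "known_cnv"):
        p = getattr(cfg, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out

        return deco

    @stage("read")
    def _read():
        return (
            read_cnv_calls(cfg.primary_calls),
            read_cnv_calls(cfg.secondary_calls),
            read_sample_table(cfg.samples),
            read_gene_models(cfg.genes),
            read_gene_sets(cfg.sets) if cfg.sets else [],
            read_bed_regions(cfg.segdups) if cfg.segdups else [],
            read_bed_regions(cfg.known_cnv) if cfg.known_cnv else [],
        )

    primary, secondary, samples, genes, sets, segdups, known = _read

    @stage("qc")
    def _qc():
        kept_samples, kept_calls, report = run_call_qc(primary, secondary, samples, cfg.qc)
        write_results(report.as_rows(), outdir / "qc_report.tsv")
        return kept_samples, kept_calls

    kept_samples, kept_calls = _qc

    @stage("stratify")
    def _strat():
        regions, common, rare = stratify_calls(
            kept_calls, len(kept_samples), cfg.frequency_threshold, cfg.direction
        )
        rare = filter_segdup(rare, segdups, cfg.qc)
        rows = [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "max_stack": r.max_stack_count,
                "frequency": r.frequency,
                "stratum": r.stratum,
            }
            for r in regions
        ]
        write_results(rows, outdir / "regions.tsv")
        return regions, common, rare

    regions, common, rare = _strat
    prov = f"seed={cfg.seed} version={__version__}"

    @stage("assoc_locus")
    def _locus():
        res = locus_association(common, kept_samples, cfg.n_perm_locus, cfg.seed)
        write_results(
            _assoc_rows(res), outdir / "locus_association.tsv",
            header_comment=f"{prov} n_perm={cfg.n_perm_locus}",
        )
        return res

    @stage("assoc_genes")
    def _genes():
        res = gene_association(rare, genes, kept_samples, cfg.n_perm_gene, cfg.seed)
        if known:
            dgv_flag(res, known, genes, alpha=cfg.fdr_threshold)
        write_results(
            _assoc_rows(res), outdir / "gene_association.tsv",
            header_comment=f"{prov} n_perm={cfg.n_perm_gene}",
        )
        return res

    @stage("burden")
    def _burden():
        res = burden_analysis(rare, kept_samples, genes, cfg.n_perm_burden, cfg.seed)
        write_results(
            res, outdir / "burden.tsv",
            header_comment=f"{prov} n_perm={cfg.n_perm_burden}",
        )
        return res

    @stage("assoc_pathways")
    def _pathways():
        if not sets:
            return []
        res = pathway_association(
            rare, genes, sets, kept_samples,
            n_perm=cfg.n_perm_pathway, seed=cfg.seed,
            min_genes=cfg.min_set_genes, max_genes=cfg.max_set_genes,
        )
        rows = [
            {
                "set_id": r.set_id,
                "name": r.name,
                "n_genes": r.n_genes,
                "posterior": r.posterior,
                "local_fdr": r.local_fdr,
                "odds_ratio": r.odds_ratio,
                "case_pct": r.case_pct,
                "control_pct": r.control_pct,
                "top_gene": r.top_gene,
            }
            for r in res
        ]
        write_results(
            rows, outdir / "pathway_association.tsv",
            header_comment=f"{prov} n_perm={cfg.n_perm_pathway}",
        )
        return res

    _ = (_locus, _genes, _burden, _pathways)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _assoc_rows(results: list[AssociationResult]) -> list[dict]:
    return [
        {
            "target": r.target,
            "case_carriers": r.table.a,
            "control_carriers": r.table.c,
            "p_unadjusted": r.p_unadjusted,
            "p_empirical": r.p_empirical,
            "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "case_pct": r.table.case_pct,
            "control_pct": r.table.control_pct,
            "dgv_false_positive": r.dgv_false_positive,
        }
        for r in results
    ]


def make_report(run_dir: str | Path, alpha: float = 0.05) -> Path:
    """Human-readable markdown summary of a completed run, with the standard
    association-table columns and rounding.  An incomplete run yields a
    partial report with warnings."""
    run_dir = Path(run_dir)
    out = run_dir / "report.md"
    lines = ["# CNV association run report", ""]
    manifest = run_dir / "manifest.json"
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        lines.append(f"Seed {meta.get('seed')}, package version {meta.get('version')}.")
        lines.append("")
    else:
        lines.append("WARNING: no manifest found; incomplete run.")
    import pandas as pd

    for title, fname, pcol in (
        ("Gene association", "gene_association.tsv", "p_empirical"),
        ("Locus association", "locus_association.tsv", "p_empirical"),
        ("Pathway association", "pathway_association.tsv", "local_fdr"),
        ("Global burden", "burden.tsv", "p"),
    ):
        f = run_dir / fname
        lines.append(f"## {title}")
        lines.append("")
        if not f.exists():
            lines.append("WARNING: stage output missing.")
            lines.append("")
            continue
        try:
            df = pd.read_csv(f, sep="\t", comment="#")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
        if df.empty:
            lines.append("No results (no associations).")
            lines.append("")
            continue
        sig = df[df[pcol] < alpha] if pcol in df.columns else df.iloc[0:0]
        if sig.empty:
            lines.append(f"No associations at {pcol} < {alpha}.")
        else:
            lines.append("```")
            lines.append(sig.to_string(index=False))
            lines.append("```")
        lines.append("")
    out.write_text("\n".join(lines))
    return out
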