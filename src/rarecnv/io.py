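"""Readers and writers for every table the pipeline touches.

Coordinate convention: **1-based, fully inclusive** everywhere inside the
package (so a call spanning positions 100..200 has length 101).  BED-style
inputs (0-based, half-open) are converted at the boundary and converted back
on write, so a well-formed BED row round-trips byte-identically.

Chromosome names are kept verbatim; comparisons are string-exact, which keeps
the package assembly-agnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

PRIMARY_CALLER = "primary_caller"
SECONDARY_CALLER = "secondary_caller"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A row parses but violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvCall:
    """One CNV event in one sample.

    ``copy_number`` must differ from the diploid normal of 2: a call is by
    definition a departure from the normal state.  The event type is derived,
    never stored: deletion iff ``copy_number < 2``, duplication iff ``> 2``.
    ``confidence`` is the caller's log-odds (LOD) score.
    """

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    copy_number: int
    n_markers: int = 1
    confidence: float = 0.0
    caller: str = PRIMARY_CALLER

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "end < start"
            )
        if self.copy_number == 2:
            raise ValidationError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "copy_number 2 is the diploid normal state, not a CNV"
            )
        if self.copy_number < 0:
            raise ValidationError("copy_number must be a non-negative integer")
        if self.n_markers < 1:
            raise ValidationError("n_markers must be a positive integer")
        if self.confidence < 0 or not math.isfinite(self.confidence):
            raise ValidationError("confidence must be a finite real >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < 2

    @property
    def is_duplication(self) -> bool:
        return self.copy_number > 2


@dataclass(frozen=True)
class SampleRecord:
    """One cohort member with phenotype and per-sample array QC metrics."""

    sample_id: str
    phenotype: str  # "case" | "control"
    n_calls: int = 0
    total_cnv_length: int = 0
    median_cn_variance: float = 0.0
    lrr_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control"):
            raise ValidationError(
                f"sample {self.sample_id}: phenotype must be 'case' or "
                f"'control', got {self.phenotype!r}"
            )

    @property
    def is_case(self) -> bool:
        return self.phenotype == "case"


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"gene {self.symbol}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id}: empty gene list")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ReferenceRegion:
    """A known-CNV reference interval (e.g. a DGV record) with a population
    frequency, or a plain annotation interval (segdup) without one."""

    chrom: str
    start: int
    end: int
    frequency: float | None = None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_CNV_TABLE_COLUMNS = (
    "sample_id",
    "chrom",
    "start",
    "end",
    "copy_number",
    "n_markers",
    "confidence",
    "caller",
)
_BED_LIKE_COLUMNS = ("chrom", "start", "end", "sample_id", "copy_number")


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_cnv_calls(
    path: str | Path,
    dialect: str = "cnv_table",
    strict: bool = True,
) -> list[CnvCall]:
    """Read a per-sample CNV call table.

    ``cnv_table`` is a headered, tab-delimited dialect with 1-based inclusive
    coordinates; ``bed_like`` is a headerless 5-column BED dialect
    (chrom, start 0-based half-open, end, sample_id, copy_number).

    With ``strict`` (default) any malformed row fails the whole read — silent
    row loss would corrupt downstream carrier counts.  ``strict=False`` skips
    malformed rows with a logged warning carrying the line number.
    """
    if dialect not in ("cnv_table", "bed_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[CnvCall] = []
    rows = list(_data_lines(path))
    if not rows:
        log.warning("%s: empty call table", path)
        return []

    colmap: dict[str, int]
    if dialect == "cnv_table":
        header = rows[0][1]
        for col in _CNV_TABLE_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing column {col!r}")
        colmap = {c: header.index(c) for c in _CNV_TABLE_COLUMNS}
        body = rows[1:]
    else:
        colmap = {c: i for i, c in enumerate(_BED_LIKE_COLUMNS)}
        body = rows

    for lineno, parts in body:
        try:
            if len(parts) < len(colmap):
                raise FormatError(
                    f"expected >= {len(colmap)} fields, got {len(parts)}"
                )
            g = lambda c: parts[colmap[c]]  # noqa: E731
            start = int(g("start"))
            end = int(g("end"))
            if dialect == "bed_like":
                if end <= start:
                    raise ValidationError("BED end must exceed BED start")
                start += 1  # 0-based half-open -> 1-based inclusive
                call = CnvCall(
                    sample_id=g("sample_id"),
                    chrom=g("chrom"),
                    start=start,
                    end=end,
                    copy_number=int(g("copy_number")),
                )
            else:
                call = CnvCall(
                    sample_id=g("sample_id"),
                    chrom=g("chrom"),
                    start=start,
                    end=end,
                    copy_number=int(g("copy_number")),
                    n_markers=int(g("n_markers")),
                    confidence=float(g("confidence")),
                    caller=g("caller"),
                )
        except (ValueError, IndexError) as exc:
            msg = f"{path}, line {lineno}: {exc}"
            if strict:
                if isinstance(exc, (FormatError, ValidationError)):
                    raise type(exc)(msg) from None
                raise FormatError(msg) from None
            log.warning("skipping malformed row: %s", msg)
            continue
        calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id))
    return calls


def write_cnv_calls(
    calls: Sequence[CnvCall], path: str | Path, dialect: str = "cnv_table"
) -> None:
    with open(path, "w") as fh:
        if dialect == "cnv_table":
            fh.write("\t".join(_CNV_TABLE_COLUMNS) + "\n")
            for c in calls:
                fh.write(
                    f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                    f"{c.copy_number}\t{c.n_markers}\t{c.confidence:g}\t"
                    f"{c.caller}\n"
                )
        elif dialect == "bed_like":
            for c in calls:
                fh.write(
                    f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.sample_id}\t"
                    f"{c.copy_number}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the sample phenotype/QC table (tab-delimited with header)."""
    rows = list(_data_lines(path))
    if not rows:
        log.warning("%s: empty sample table", path)
        return []
    header = rows[0][1]
    required = (
        "sample_id",
        "phenotype",
        "n_calls",
        "total_cnv_length",
        "median_cn_variance",
        "lrr_sd",
    )
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing column {col!r}")
    idx = {c: header.index(c) for c in required}
    samples = []
    seen: set[str] = set()
    for lineno, parts in rows[1:]:
        sid = parts[idx["sample_id"]]
        if sid in seen:
            raise ValidationError(f"{path}, line {lineno}: duplicate sample {sid}")
        seen.add(sid)
        samples.append(
            SampleRecord(
                sample_id=sid,
                phenotype=parts[idx["phenotype"]],
                n_calls=int(parts[idx["n_calls"]]),
                total_cnv_length=int(parts[idx["total_cnv_length"]]),
                median_cn_variance=float(parts[idx["median_cn_variance"]]),
                lrr_sd=float(parts[idx["lrr_sd"]]),
            )
        )
    return samples


def write_sample_table(samples: Sequence[SampleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tphenotype\tn_calls\ttotal_cnv_length\t"
            "median_cn_variance\tlrr_sd\n"
        )
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.phenotype}\t{s.n_calls}\t"
                f"{s.total_cnv_length}\t{s.median_cn_variance:g}\t{s.lrr_sd:g}\n"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from 4-column BED (chrom, start, end, symbol)."""
    genes: list[GeneModel] = []
    seen: dict[str, tuple] = {}
    for lineno, parts in _data_lines(path):
        if len(parts) < 4:
            raise FormatError(f"{path}, line {lineno}: expected 4 BED columns")
        chrom, start, end, symbol = parts[0], int(parts[1]), int(parts[2]), parts[3]
        if end <= start:
            raise ValidationError(
                f"{path}, line {lineno}: zero/negative-length feature {symbol}"
            )
        if symbol in seen and seen[symbol] != (chrom, start, end):
            log.warning(
                "%s, line %d: duplicate symbol %s at a different locus; kept",
                path,
                lineno,
                symbol,
            )
        seen[symbol] = (chrom, start, end)
        genes.append(GeneModel(symbol=symbol, chrom=chrom, start=start + 1, end=end))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.symbol))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (set_id, description, gene, gene, ...)."""
    sets: list[GeneSet] = []
    for lineno, parts in _data_lines(path):
        if len(parts) < 3:
            raise FormatError(
                f"{path}, line {lineno}: GMT line needs >= 3 fields "
                "(set_id, description, at least one gene)"
            )
        set_id, name, genes = parts[0], parts[1], [p for p in parts[2:] if p]
        if not genes:
            raise FormatError(f"{path}, line {lineno}: set {set_id} has no genes")
        if len(set(genes)) < len(genes):
            log.warning(
                "%s, line %d: duplicate genes in set %s deduplicated",
                path,
                lineno,
                set_id,
            )
        sets.append(GeneSet(set_id=set_id, name=name, genes=frozenset(genes)))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(f"{s.set_id}\t{s.name}\t" + "\t".join(sorted(s.genes)) + "\n")


def read_bed_regions(path: str | Path) -> list[ReferenceRegion]:
    """Read annotation intervals from BED; an optional 4th numeric column is
    interpreted as a population frequency (known-CNV reference dialect)."""
    regions = []
    warned = False
    for lineno, parts in _data_lines(path):
        if len(parts) < 3:
            raise FormatError(f"{path}, line {lineno}: expected >= 3 BED columns")
        freq: float | None = None
        if len(parts) >= 4:
            try:
                freq = float(parts[3])
            except ValueError:
                if not warned:
                    log.warning("%s: non-numeric 4th column ignored", path)
                    warned = True
        regions.append(
            ReferenceRegion(
                chrom=parts[0], start=int(parts[1]) + 1, end=int(parts[2]), frequency=freq
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def write_bed_regions(regions: Sequence[ReferenceRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            line = f"{r.chrom}\t{r.start - 1}\t{r.end}"
            if r.frequency is not None:
                line += f"\t{r.frequency:g}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def format_p(p: float) -> str:
    """Two-significant-digit scientific notation, e.g. 0.0039014 -> '3.9e-03'."""
    return f"{p:.1e}"


def format_or(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:.2f}"


def format_pct(x: float) -> str:
    return f"{x:.1f}"


_P_FIELDS = ("p", "p_unadjusted", "p_empirical", "local_fdr", "posterior")
_OR_FIELDS = ("odds_ratio", "ci_low", "ci_high", "ratio", "z")
_PCT_SUFFIX = "_pct"


def _display(name: str, value) -> str | None:
    if name not in _P_FIELDS and name not in _OR_FIELDS and not name.endswith(_PCT_SUFFIX):
        return None
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if name in _P_FIELDS:
        return format_p(value)
    if name in _OR_FIELDS:
        return format_or(value)
    return format_pct(value)


def write_results(
    records: Sequence,
    path: str | Path,
    header_comment: str = "",
    columns: Sequence[str] | None = None,
) -> None:
    """Write a homogeneous list of result dataclasses (or dicts) as TSV.

    Numeric fields are written at full precision; p-value, odds-ratio and
    percentage fields additionally get a ``<name>_display`` column rounded
    the way association tables are conventionally printed (p to 2 significant
    digits, OR to 2 decimals, percentages to 1 decimal).
    """
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        if not records:
            fh.write("\t".join(columns) + "\n" if columns else "")
            return
        first = records[0]
        if hasattr(first, "__dataclass_fields__"):
            names = [f.name for f in fields(first)]
            rows = [{n: getattr(r, n) for n in names} for r in records]
        else:
            names = list(first.keys())
            rows = [dict(r) for r in records]
        out_cols: list[str] = []
        for n in names:
            out_cols.append(n)
            if _display(n, rows[0].get(n, None)) is not None:
                out_cols.append(n + "_display")
        fh.write("\t".join(out_cols) + "\n")
        for row in rows:
            cells = []
            for n in names:
                v = row.get(n)
                cells.append("NA" if v is None else str(v))
                d = _display(n, v)
                if d is not None:
                    cells.append(d)
            fh.write("\t".join(cells) + "\n")
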