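"""A small built-in worked example: rare CNVs hitting a cell-migration gene
set in a 189-case / 380-control cohort.

The 16 CNV calls (coordinates, copy numbers, sample ids) reproduce a
published worked example of a cell-migration gene set hit by rare CNVs at 13
unique loci in 10 cases and 6 controls.  The gene models are SYNTHETIC
stand-ins: real gene coordinates are not part of the example, so each gene
is placed inside (or spanning) the calls it must overlap, reproducing the
printed call-to-gene overlap pattern exactly — 14 distinct genes, of which
PTPRK and CDH13 are each hit by two different case calls, and MUC2/MUC5AC
are hit by the same single call.
"""

from __future__ import annotations

from .io import CnvCall, GeneModel, GeneSet, SampleRecord

_CALLS = [
    # (chrom, start, end, copy_number, sample_id, is_case)
    ("chr4", 55607652, 55616597, 1, "165855", True),
    ("chr6", 128485528, 128525520, 1, "232996", True),
    ("chr6", 128864684, 128871092, 1, "190037", True),
    ("chr11", 1094626, 1140711, 3, "210711", True),
    ("chr16", 29474810, 30099408, 1, "124873", True),
    ("chr16", 29488112, 30085920, 1, "233682", True),
    ("chr16", 82119367, 82175095, 1, "224567", True),
    ("chr16", 82408574, 82502970, 1, "232030", True),
    ("chr18", 52763504, 53341297, 3, "203688", True),
    ("chr18", 59018003, 59031365, 1, "231734", True),
    ("chr2", 55119289, 56699138, 3, "M3088A", False),
    ("chr3", 188880305, 188936673, 3, "M1270A", False),
    ("chr12", 50532205, 50579767, 3, "M3576A", False),
    ("chr15", 50811752, 50882082, 3, "M3047A", False),
    ("chr15", 97371582, 97730964, 3, "M053A", False),
    ("chr19", 49893892, 50298979, 3, "M3381A", False),
]

# synthetic gene stand-ins placed to reproduce the printed overlap pattern
_GENES = [
    ("KDR", "chr4", 55600000, 55620000),
    ("RTN4", "chr2", 55500000, 55600000),
    ("SST", "chr3", 188900000, 188910000),
    ("PTPRK", "chr6", 128480000, 128900000),
    ("MUC2", "chr11", 1095000, 1110000),
    ("MUC5AC", "chr11", 1115000, 1135000),
    ("ACVRL1", "chr12", 50540000, 50560000),
    ("ONECUT1", "chr15", 50820000, 50860000),
    ("IGF1R", "chr15", 97400000, 97700000),
    ("CORO1A", "chr16", 30000000, 30010000),
    ("CDH13", "chr16", 82100000, 82510000),
    ("ONECUT2", "chr18", 53000000, 53050000),
    ("BCL2", "chr18", 59018003, 59031365),
    ("APOE", "chr19", 50100000, 50104000),
]

N_CASES = 189
N_CONTROLS = 380


def cell_migration_example() -> tuple[
    list[CnvCall], list[GeneModel], GeneSet, list[SampleRecord]
]:
    """The worked-example fixture: 16 rare calls, 14 gene stand-ins, the
    cell-migration gene set and a 189/380 cohort containing the carriers."""
    calls = [
        CnvCall(
            sample_id=sid,
            chrom=chrom,
            start=start,
            end=end,
            copy_number=cn,
            n_markers=50,
            confidence=10.0,
        )
        for chrom, start, end, cn, sid, _ in _CALLS
    ]
    genes = [GeneModel(symbol=s, chrom=c, start=a, end=b) for s, c, a, b in _GENES]
    gene_set = GeneSet(
        set_id="go:0030334",
        name="regulation of cell migration",
        genes=frozenset(g[0] for g in _GENES),
    )
    case_ids = [sid for _, _, _, _, sid, is_case in _CALLS if is_case]
    control_ids = [sid for _, _, _, _, sid, is_case in _CALLS if not is_case]
    # de-duplicate while preserving order (two calls may share a sample)
    case_ids = list(dict.fromkeys(case_ids))
    control_ids = list(dict.fromkeys(control_ids))
    case_ids += [f"CASEF{i:04d}" for i in range(N_CASES - len(case_ids))]
    control_ids += [f"CTRLF{i:04d}" for i in range(N_CONTROLS - len(control_ids))]
    samples = [SampleRecord(sample_id=s, phenotype="case") for s in case_ids] + [
        SampleRecord(sample_id=s, phenotype="control") for s in control_ids
    ]
    return calls, genes, gene_set, samples
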