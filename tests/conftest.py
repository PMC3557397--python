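import numpy as np
import pytest

from rarecnv.datasets import cell_migration_example
from rarecnv.io import CnvCall, SampleRecord


@pytest.fixture(scope="session")
def cell_migration():
    """The built-in worked example: 16 rare calls, 14 genes, the
    cell-migration set and a 189/380 cohort."""
    calls, genes, gene_set, samples = cell_migration_example()
    return {"calls": calls, "genes": genes, "set": gene_set, "samples": samples}


def make_call(
    sample_id="S1",
    chrom="chr1",
    start=100,
    end=199,
    copy_number=1,
    n_markers=10,
    confidence=5.0,
    caller="primary_caller",
):
    return CnvCall(
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=end,
        copy_number=copy_number,
        n_markers=n_markers,
        confidence=confidence,
        caller=caller,
    )


def make_cohort(n_cases, n_controls):
    return [
        SampleRecord(sample_id=f"CASE{i}", phenotype="case") for i in range(n_cases)
    ] + [
        SampleRecord(sample_id=f"CTRL{i}", phenotype="control")
        for i in range(n_controls)
    ]
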