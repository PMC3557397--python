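"""Consensus and QC cascade: overlap rules, boundary semantics, segdup union."""

import numpy as np
import pytest

from rarecnv.io import ReferenceRegion, SampleRecord
from rarecnv.qc import (
    QcConfig,
    consensus_calls,
    filter_call_quality,
    filter_samples,
    filter_segdup,
    overlap_fraction,
    run_call_qc,
    segdup_fraction,
)

from .conftest import make_call


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "b_start,b_end,expected",
        [
            (100, 199, 1.0),  # identity
            (300, 400, 0.0),  # disjoint
            (150, 249, 0.5),  # shared bases 150..199 = 50 of 100
        ],
    )
    def test_examples(self, b_start, b_end, expected):
        a = make_call(start=100, end=199)
        b = make_call(start=b_start, end=b_end, caller="secondary_caller")
        assert overlap_fraction(a, b) == expected

    def test_different_chromosomes_zero(self):
        a = make_call(chrom="chr1")
        b = make_call(chrom="chr2")
        assert overlap_fraction(a, b) == 0.0

    def test_asymmetric_denominator(self):
        a = make_call(start=100, end=119)  # 20 bases
        b = make_call(start=100, end=199)  # 100 bases
        assert overlap_fraction(a, b) == 1.0
        assert overlap_fraction(b, a) == 0.2


class TestConsensus:
    def test_identical_call_kept(self):
        a = make_call()
        b = make_call(caller="secondary_caller")
        assert consensus_calls([a], [b]) == [a]

    def test_direction_mismatch_dropped(self):
        deletion = make_call(copy_number=1)
        duplication = make_call(copy_number=3, caller="secondary_caller")
        assert consensus_calls([deletion], [duplication]) == []

    def test_ten_percent_threshold_boundary(self):
        a = make_call(start=1, end=100)  # 100 bases
        at_9pct = make_call(start=92, end=300, caller="secondary_caller")
        at_10pct = make_call(start=91, end=300, caller="secondary_caller")
        assert consensus_calls([a], [at_9pct]) == []
        assert consensus_calls([a], [at_10pct]) == [a]

    def test_sample_in_one_caller_only_dropped(self, caplog):
        a = make_call(sample_id="ONLY_PRIMARY")
        with caplog.at_level("WARNING"):
            assert consensus_calls([a], []) == []
        assert "ONLY_PRIMARY" in caplog.text

    def test_primary_boundaries_retained(self):
        a = make_call(start=100, end=199)
        b = make_call(start=150, end=260, caller="secondary_caller")
        (kept,) = consensus_calls([a], [b])
        assert (kept.start, kept.end) == (100, 199)

    def test_idempotent(self):
        primary = [make_call(), make_call(sample_id="S2", start=500, end=9000)]
        secondary = [
            make_call(caller="secondary_caller"),
            make_call(sample_id="S2", start=600, end=9100, caller="secondary_caller"),
        ]
        once = consensus_calls(primary, secondary)
        assert consensus_calls(once, secondary) == once


class TestCallQuality:
    def test_lod_exactly_two_removed(self):
        call = make_call(start=1, end=10000, confidence=2.0)
        assert filter_call_quality([call]) == []

    def test_four_kb_five_markers_kept(self):
        call = make_call(start=1, end=4000, n_markers=5, confidence=2.1)
        assert filter_call_quality([call]) == [call]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"start": 1, "end": 3999},  # < 4 kb
            {"start": 1, "end": 10000, "n_markers": 4},  # < 5 markers
            {"start": 1, "end": 1_000_001},  # > 1 Mb
        ],
    )
    def test_size_and_marker_exclusions(self, kwargs):
        assert filter_call_quality([make_call(confidence=5.0, **kwargs)]) == []

    def test_exactly_one_megabase_kept(self):
        call = make_call(start=1, end=1_000_000, n_markers=100, confidence=5.0)
        assert filter_call_quality([call]) == [call]


class TestSampleFilters:
    def _sample(self, sid="S1", **kw):
        defaults = dict(phenotype="case", median_cn_variance=0.5, lrr_sd=0.2)
        defaults.update(kw)
        return SampleRecord(sample_id=sid, **defaults)

    def test_111_calls_removed_110_kept(self):
        for n, expect_kept in ((111, 0), (110, 1)):
            calls = [
                make_call(sample_id="S1", start=1 + 10_000 * i, end=9_000 + 10_000 * i)
                for i in range(n)
            ]
            kept_samples, kept_calls, report = filter_samples(calls, [self._sample()])
            assert len(kept_samples) == expect_kept
            assert len(kept_calls) == (n if expect_kept else 0)

    def test_lrr_sd_boundary_is_strict(self):
        kept, _, _ = filter_samples([make_call()], [self._sample(lrr_sd=0.4)])
        assert len(kept) == 1
        kept, _, _ = filter_samples([make_call()], [self._sample(lrr_sd=0.41)])
        assert kept == []

    def test_total_length_rule(self):
        big = make_call(start=1, end=7_500_001)  # just over 7.5 Mb
        kept, _, _ = filter_samples([big], [self._sample()])
        assert kept == []

    def test_clean_cohort_is_identity(self):
        calls = [make_call(sample_id="S1"), make_call(sample_id="S2", start=5000, end=9000)]
        samples = [self._sample("S1"), self._sample("S2")]
        kept_samples, kept_calls, _ = filter_samples(calls, samples)
        assert len(kept_samples) == 2 and kept_calls == calls

    def test_missing_metrics_names_sample(self):
        with pytest.raises(KeyError, match="GHOST"):
            filter_samples([make_call(sample_id="GHOST")], [self._sample("S1")])


class TestSegdupFilter:
    def test_fully_inside_segdup_removed(self):
        call = make_call(start=100, end=199)
        seg = [ReferenceRegion("chr1", 50, 300)]
        assert filter_segdup([call], seg) == []

    def test_union_coverage_exactly_half_kept(self):
        # two fragments covering 30%+30% with 10% mutual overlap -> union 50%
        call = make_call(start=1, end=100)
        segs = [ReferenceRegion("chr1", 1, 30), ReferenceRegion("chr1", 21, 50)]
        assert segdup_fraction(call, segs) == 0.5
        assert filter_segdup([call], segs) == [call]

    def test_empty_reference_is_identity(self):
        calls = [make_call()]
        assert filter_segdup(calls, []) == calls

    def test_kept_calls_satisfy_brute_force_coverage(self):
        # per-base oracle on random fixtures: every kept call has <= 50% cover
        rng = np.random.default_rng(42)
        segs = [
            ReferenceRegion("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(1, 9000, 40), rng.integers(10, 400, 40))
        ]
        calls = [
            make_call(start=int(s), end=int(s) + 99)
            for s in rng.integers(1, 9000, 30)
        ]
        kept = filter_segdup(calls, segs)
        covered = np.zeros(12_000, dtype=bool)
        for r in segs:
            covered[r.start : r.end + 1] = True
        for c in calls:
            frac = covered[c.start : c.end + 1].mean()
            assert (c in kept) == (frac <= 0.5)


class TestQcReport:
    def test_removals_sum_to_input_minus_output(self):
        primary = [
            make_call(sample_id="S1"),
            make_call(sample_id="S1", start=5000, end=5100, confidence=1.0),
            make_call(sample_id="S2", start=1, end=9000),
            make_call(sample_id="S3", start=1, end=9000),
        ]
        secondary = [
            make_call(sample_id="S1", caller="secondary_caller"),
            make_call(sample_id="S1", start=5000, end=5100, caller="secondary_caller"),
            make_call(sample_id="S2", start=1, end=9000, caller="secondary_caller"),
        ]
        samples = [
            SampleRecord("S1", "case", median_cn_variance=0.5, lrr_sd=0.2),
            SampleRecord("S2", "control", median_cn_variance=5.0, lrr_sd=0.2),
            SampleRecord("S3", "control", median_cn_variance=0.5, lrr_sd=0.2),
        ]
        kept_samples, kept_calls, report = run_call_qc(primary, secondary, samples)
        call_removals = report.total_removed("not_in_both") + report.total_removed(
            "call_quality"
        ) + report.total_removed("calls_of_removed")
        assert call_removals == len(primary) - len(kept_calls)
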