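"""Exact 2x2 inference, carrier counting, min-p permutation, burden."""

import itertools

import numpy as np
import pytest
from scipy import stats

from rarecnv.association import (
    CarrierTable,
    burden_metrics,
    burden_permutation,
    dgv_flag,
    fisher_exact,
    gene_association,
    gene_carrier_counts,
    locus_association,
    locus_scan,
    minp_permutation,
    odds_ratio_cmle,
)
from rarecnv.io import GeneModel, ReferenceRegion

from .conftest import make_call, make_cohort


def enumeration_fisher(t: CarrierTable) -> float:
    """Independent oracle: enumerate every table with the observed margins
    and sum the hypergeometric probabilities <= the observed one."""
    m, n_cases, n = t.n_carriers, t.n_cases, t.n_total
    lo = max(0, m - t.n_controls)
    hi = min(m, n_cases)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, n, m, n_cases)
    p_obs = probs[t.a - lo]
    return min(1.0, float(probs[probs <= p_obs * (1 + 1e-7)].sum()))


class TestFisherExact:
    def test_worked_examples(self):
        # printed worked examples: 5/189 vs 0/380 and 7/189 vs 0/380
        assert fisher_exact(CarrierTable(5, 184, 0, 380)) == pytest.approx(3.9e-3, rel=0.02)
        assert fisher_exact(CarrierTable(7, 182, 0, 380)) == pytest.approx(4.1e-4, rel=0.02)

    def test_zero_margin_is_one(self):
        assert fisher_exact(CarrierTable(0, 10, 0, 20)) == 1.0

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, 4))
            t = CarrierTable(a, b, c, d)
            assert fisher_exact(t) == pytest.approx(enumeration_fisher(t), rel=1e-7)


def conditional_lik_grid(t: CarrierTable) -> float:
    """Oracle: grid-search maximizer of the noncentral hypergeometric
    conditional likelihood over psi in 10^[-3, 3]."""
    m, ncs, n = t.n_carriers, t.n_cases, t.n_total
    lo = max(0, m - t.n_controls)
    hi = min(m, ncs)
    support = np.arange(lo, hi + 1)
    from scipy.special import comb

    weights = comb(ncs, support) * comb(t.n_controls, m - support)
    psis = np.logspace(-3, 3, 20001)
    ll = t.a * np.log(psis) - np.log(
        (weights[None, :] * psis[:, None] ** support[None, :]).sum(axis=1)
    )
    return float(psis[np.argmax(ll)])


class TestOddsRatio:
    def test_worked_example(self):
        est, lo, hi = odds_ratio_cmle(CarrierTable(10, 179, 6, 374))
        assert est == pytest.approx(3.47, abs=0.005)
        assert lo == pytest.approx(1.12, abs=0.01)
        assert hi == pytest.approx(11.82, abs=0.01)

    def test_symmetric_table_is_one(self):
        est, _, _ = odds_ratio_cmle(CarrierTable(4, 16, 4, 16))
        assert est == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        t = CarrierTable(3, 7, 1, 9)
        est, _, _ = odds_ratio_cmle(t)
        assert est == pytest.approx(conditional_lik_grid(t), rel=1e-3)

    def test_zero_control_cell_infinite_with_finite_lower_bound(self):
        est, lo, hi = odds_ratio_cmle(CarrierTable(5, 184, 0, 380))
        assert np.isinf(est) and np.isinf(hi)
        assert 0 < lo < np.inf

    def test_no_carriers_is_missing(self):
        assert odds_ratio_cmle(CarrierTable(0, 10, 0, 20)) == (None, None, None)


class TestMinpPermutation:
    def test_formula_floor(self):
        # observed battery beats every permutation minimum
        def battery(mask):
            return np.array([1e-12 if mask[0] else 0.5])

        phen = np.array([True] + [False] * 19)
        p = minp_permutation(battery, phen, n_perm=999, seed=0)
        assert p[0] >= 1 / 1000

    def test_p_one_stays_one(self):
        battery = lambda mask: np.array([1.0])  # noqa: E731
        p = minp_permutation(battery, np.array([True, False] * 10), 99, seed=1)
        assert p[0] == 1.0

    def test_monotone_in_unadjusted_p(self):
        rng = np.random.default_rng(5)
        m = rng.random((30, 8)) < 0.3

        def battery(mask):
            a = mask.astype(float) @ m
            return 1.0 / (1.0 + a)  # deterministic surrogate p

        phen = np.array([True] * 10 + [False] * 20)
        p_obs = battery(phen)
        p_emp = minp_permutation(battery, phen, 200, seed=2)
        order = np.argsort(p_obs)
        assert np.all(np.diff(p_emp[order]) >= 0)

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            minp_permutation(lambda m: np.array([1.0]), np.array([True, False]), 0, 0)

    def test_null_empirical_p_stochastically_uniform_or_larger(self):
        # 20-sample null fixture: P(p_emp <= q) should not exceed q by much
        rng = np.random.default_rng(9)
        m = rng.random((20, 5)) < 0.4
        phen = np.array([True] * 10 + [False] * 10)

        def battery(mask):
            a = mask.astype(float) @ m
            return 1.0 / (1.0 + a)

        hits = 0
        for rep in range(50):
            perm_phen = np.random.default_rng(100 + rep).permutation(phen)
            p = minp_permutation(battery, perm_phen, 200, seed=rep)
            hits += int(p.min() < 0.05)
        assert hits / 50 <= 0.10


class TestGeneCarriers:
    def test_two_calls_one_gene_counts_once(self):
        gene = GeneModel("G1", "chr1", 1000, 2000)
        calls = [
            make_call(sample_id="CASE0", start=900, end=1100),
            make_call(sample_id="CASE0", start=1500, end=2600),
        ]
        t = gene_carrier_counts(calls, [gene], make_cohort(5, 5))["G1"]
        assert (t.a, t.c) == (1, 0)

    def test_worked_example_pattern(self, cell_migration):
        counts = gene_carrier_counts(
            cell_migration["calls"], cell_migration["genes"], cell_migration["samples"]
        )
        assert (counts["PTPRK"].a, counts["PTPRK"].c) == (2, 0)
        assert (counts["CDH13"].a, counts["CDH13"].c) == (2, 0)
        assert (counts["MUC2"].a, counts["MUC5AC"].a) == (1, 1)
        assert sum(t.a + t.c for t in counts.values()) >= 14

    def test_adjacent_but_not_overlapping_is_not_carrier(self):
        gene = GeneModel("G1", "chr1", 1000, 2000)
        near_miss = make_call(sample_id="CASE0", start=1, end=999)
        touch = make_call(sample_id="CASE1", start=1, end=1000)
        counts = gene_carrier_counts([near_miss, touch], [gene], make_cohort(5, 5))
        assert counts["G1"].a == 1  # only the one-base overlap


class TestGeneAssociation:
    def test_planted_gene_recovers_worked_p(self):
        gene = GeneModel("G1", "chr1", 1000, 2000)
        samples = make_cohort(189, 380)
        calls = [
            make_call(sample_id=f"CASE{i}", start=900, end=2100) for i in range(5)
        ]
        (res,) = gene_association(calls, [gene], samples, n_perm=99, seed=0)
        assert res.p_unadjusted == pytest.approx(3.9e-3, rel=0.02)

    def test_single_gene_battery_degenerates(self):
        gene = GeneModel("G1", "chr1", 1000, 2000)
        samples = make_cohort(20, 20)
        calls = [make_call(sample_id=f"CASE{i}", start=900, end=2100) for i in range(6)]
        (res,) = gene_association(calls, [gene], samples, n_perm=499, seed=3)
        # battery of one: empirical p estimates the unadjusted p itself
        assert res.p_empirical == pytest.approx(res.p_unadjusted, abs=0.05)

    def test_zero_carrier_genes_skipped(self):
        genes = [GeneModel("G1", "chr1", 1000, 2000), GeneModel("G2", "chr9", 1, 100)]
        calls = [make_call(sample_id="CASE0", start=900, end=2100)]
        res = gene_association(calls, genes, make_cohort(5, 5), n_perm=19, seed=0)
        assert [r.target for r in res] == ["G1"]


class TestDgvFlag:
    def _result(self, gene="G1", a=5, p_emp=0.01):
        from rarecnv.association import AssociationResult

        return AssociationResult(
            target=gene,
            table=CarrierTable(a, 189 - a, 0, 380),
            p_unadjusted=0.001,
            p_empirical=p_emp,
        )

    def test_known_locus_flagged(self):
        genes = [GeneModel("G1", "chr8", 1000, 2000)]
        ref = [ReferenceRegion("chr8", 900, 1500, frequency=0.05)]
        (res,) = dgv_flag([self._result()], ref, genes)
        assert res.dgv_false_positive  # prior frequency >= case frequency

    def test_novel_locus_not_flagged(self):
        genes = [GeneModel("G1", "chr20", 1000, 2000)]
        ref = [ReferenceRegion("chr8", 900, 1500, frequency=0.05)]
        (res,) = dgv_flag([self._result()], ref, genes)
        assert not res.dgv_false_positive

    def test_reference_without_frequency_warns(self, caplog):
        genes = [GeneModel("G1", "chr8", 1000, 2000)]
        ref = [ReferenceRegion("chr8", 900, 1500)]
        with caplog.at_level("WARNING"):
            (res,) = dgv_flag([self._result()], ref, genes)
        assert not res.dgv_false_positive
        assert "frequency" in caplog.text

    def test_empty_reference_no_flags(self):
        genes = [GeneModel("G1", "chr8", 1000, 2000)]
        (res,) = dgv_flag([self._result()], [], genes)
        assert not res.dgv_false_positive


class TestLocusScan:
    def test_single_region_collapses_to_one_test(self):
        samples = make_cohort(20, 20)
        calls = [
            make_call(sample_id=f"CASE{i}", start=100, end=199) for i in range(6)
        ] + [make_call(sample_id=f"CTRL{i}", start=100, end=199) for i in range(2)]
        results, _ = locus_scan(calls, samples)
        assert len(results) == 1
        t = results[0].table
        assert (t.a, t.c) == (6, 2)
        assert results[0].p_unadjusted == pytest.approx(
            fisher_exact(CarrierTable(6, 14, 2, 18))
        )

    def test_direction_filter_yields_empty(self):
        samples = make_cohort(5, 5)
        deletions = [make_call(sample_id="CASE0", start=1, end=100)]
        results, _ = locus_scan(deletions, samples, direction="dup")
        assert results == []

    def test_boundary_truncation_edges_excluded(self):
        # 3 samples share a core; one extends further left only by truncation
        samples = make_cohort(3, 3)
        calls = [
            make_call(sample_id="CASE0", start=50, end=200),
            make_call(sample_id="CASE1", start=100, end=200),
            make_call(sample_id="CTRL0", start=100, end=200),
        ]
        results, _ = locus_scan(calls, samples)
        # the [50,99] edge locus (CASE0 only, subset of the core) is dropped
        assert len(results) == 1
        assert results[0].locus[1:] == (100, 200)

    def test_permutation_wrapper_runs(self):
        samples = make_cohort(10, 10)
        calls = [make_call(sample_id=f"CASE{i}", start=1, end=100) for i in range(5)]
        res = locus_association(calls, samples, n_perm=49, seed=0)
        assert len(res) == 1 and 0 < res[0].p_empirical <= 1


class TestBurden:
    def test_per_sample_arithmetic(self):
        samples = make_cohort(1, 1)
        calls = [
            make_call(sample_id="CASE0", start=1, end=10_000),
            make_call(sample_id="CASE0", start=50_000, end=80_000, copy_number=3),
        ]
        table, _ = burden_metrics(calls, samples, [])
        assert table[("rate", "all")][0] == 2
        assert table[("mean_length", "all")][0] == pytest.approx(20_000.5)
        assert table[("total_length", "all")][0] == 40_001
        assert table[("rate", "del_only")][0] == 1
        assert table[("rate", "dup_only")][0] == 1
        # zero-call sample: zero rate, NaN mean length
        assert table[("rate", "all")][1] == 0
        assert np.isnan(table[("mean_length", "all")][1])

    def test_gene_rate_counts_distinct_genes(self):
        genes = [GeneModel("G1", "chr1", 1, 500), GeneModel("G2", "chr1", 600, 900)]
        calls = [
            make_call(sample_id="CASE0", start=400, end=800),  # hits both
            make_call(sample_id="CASE0", start=5_000, end=6_000),  # hits none
        ]
        table, _ = burden_metrics(calls, make_cohort(1, 1), genes)
        assert table[("gene_rate", "all")][0] == 2

    def test_symmetric_distribution_p_near_half(self):
        rng = np.random.default_rng(1)
        samples = make_cohort(50, 50)
        calls = []
        for s in samples:
            for _ in range(int(rng.poisson(3))):
                start = int(rng.integers(1, 100_000))
                calls.append(make_call(sample_id=s.sample_id, start=start, end=start + 5_000))
        table, _ = burden_metrics(calls, samples, [])
        p = burden_permutation(table, samples, n_perm=2000, seed=2)[("rate", "all")]
        assert 0.2 < p < 0.8

    def test_extreme_separation_hits_floor(self):
        samples = make_cohort(5, 5)
        calls = [
            make_call(sample_id=f"CASE{i}", start=1 + 10_000 * j, end=9_000 + 10_000 * j)
            for i in range(5)
            for j in range(4)
        ]
        table, _ = burden_metrics(calls, samples, [])
        p = burden_permutation(table, samples, n_perm=500, seed=3)[("rate", "all")]
        assert p == pytest.approx(1 / 501, abs=0.01)

    def test_metric_multiset_conserved_under_relabeling(self):
        rng = np.random.default_rng(4)
        samples = make_cohort(10, 10)
        calls = [
            make_call(sample_id=s.sample_id, start=int(p), end=int(p) + 4_000)
            for s in samples
            for p in rng.integers(1, 50_000, int(rng.poisson(2)))
        ]
        table, _ = burden_metrics(calls, samples, [])
        x = table[("rate", "all")]
        shuffled = [samples[i] for i in rng.permutation(len(samples))]
        table2, _ = burden_metrics(calls, shuffled, [])
        assert sorted(x) == sorted(table2[("rate", "all")])

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            burden_metrics([], [], [])
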