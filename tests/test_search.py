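"""Exhaustive and stepwise scan engines against an independent brute-force oracle."""

import math

import numpy as np
import pytest
from oracles import oracle_scan

from igscan.io import MISSING, GenotypeMatrix
from igscan.search import (
    ExhaustiveIGScan,
    SearchConfig,
    StepwiseIGScan,
    contingency_table,
    rank_results,
    scan_exhaustive,
    scan_stepwise,
)
from igscan.simulate import builtin_model, simulate_case_control


# --- contingency counting ---------------------------------------------------

class TestContingencyTable:
    def test_hand_counted_pair(self):
        geno = np.array(
            [[0, 0], [0, 0], [1, 0], [1, 2], [1, 2], [2, 2], [2, 2], [2, 2]],
            dtype=np.int8,
        )
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1], dtype=np.int8)
        ct = contingency_table(GenotypeMatrix(geno, y), (0, 1))
        # joint cells (g1,g2): (0,0)x2, (1,0)x1, (1,2)x2, (2,2)x3
        assert ct.counts.tolist() == [[1, 1], [1, 0], [0, 2], [2, 1]]
        assert ct.n_total == 8

    def test_constant_snp_single_row(self):
        g = GenotypeMatrix(np.zeros((10, 1), dtype=np.int8), np.repeat([0, 1], 5))
        ct = contingency_table(g, (0,))
        assert ct.counts.shape == (1, 2)

    def test_sample_order_invariance(self, small_null_matrix, rng):
        ct1 = contingency_table(small_null_matrix, (2, 5))
        perm = rng.permutation(small_null_matrix.n_samples)
        g2 = GenotypeMatrix(
            small_null_matrix.genotypes[perm], small_null_matrix.phenotype[perm]
        )
        ct2 = contingency_table(g2, (2, 5))
        assert np.array_equal(ct1.counts, ct2.counts)

    def test_missing_excluded(self):
        geno = np.array([[0], [1], [MISSING]], dtype=np.int8)
        ct = contingency_table(GenotypeMatrix(geno, np.array([0, 1, 1])), (0,))
        assert ct.n_total == 2

    def test_duplicate_indices_rejected(self, small_null_matrix):
        with pytest.raises(ValueError):
            contingency_table(small_null_matrix, (1, 1))


# --- exhaustive scan --------------------------------------------------------

class TestExhaustiveScan:
    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_oracle_equivalence(self, order, rng):
        geno = rng.binomial(2, rng.uniform(0.1, 0.5, 12), size=(80, 12)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.02] = MISSING
        y = rng.integers(0, 2, 80).astype(np.int8)
        est = ExhaustiveIGScan(order=order, keep_all=True).fit(geno, y)
        expected = oracle_scan(geno, y, order)
        assert len(est.all_results_) == math.comb(12, order)
        for res in est.all_results_:
            ig, levels, n, p = expected[res.snp_indices]
            assert res.ig_bits == pytest.approx(ig, abs=1e-12)
            assert res.levels_x == levels
            assert res.n_complete == n
            assert res.p_raw == pytest.approx(p, abs=1e-10)
            assert res.p_adjusted == pytest.approx(
                min(1.0, math.comb(12, order) * p), abs=1e-9
            )
        # identical ranking to the oracle's sort
        oracle_order = sorted(
            expected, key=lambda idx: (expected[idx][3], -expected[idx][0], idx)
        )
        assert [r.snp_indices for r in est.all_results_] == oracle_order

    def test_planted_signal_ranked_first(self, planted_pair_matrix):
        results = scan_exhaustive(planted_pair_matrix, order=2)
        assert results, "planted pair should reach significance"
        assert results[0].snp_indices == (3, 7)
        assert results[0].p_adjusted < 1e-6

    def test_alpha_zero_empty(self, planted_pair_matrix):
        assert scan_exhaustive(planted_pair_matrix, order=2, alpha=0.0) == []

    def test_column_permutation_invariance(self, planted_pair_matrix, rng):
        perm = rng.permutation(planted_pair_matrix.n_snps)
        g2 = GenotypeMatrix(
            planted_pair_matrix.genotypes[:, perm], planted_pair_matrix.phenotype
        )
        r1 = scan_exhaustive(planted_pair_matrix, order=2, keep_all=True)
        r2 = scan_exhaustive(g2, order=2, keep_all=True)
        relabel = {int(p): i for i, p in enumerate(perm)}
        mapped = {
            tuple(sorted(relabel[i] for i in r.snp_indices)): r.ig_bits for r in r1
        }
        for res in r2:
            assert res.ig_bits == pytest.approx(mapped[res.snp_indices], abs=1e-9)

    def test_order_exceeding_snps_rejected(self, small_null_matrix):
        with pytest.raises(ValueError):
            scan_exhaustive(small_null_matrix, order=21)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ExhaustiveIGScan().fit(np.array([[0, 4], [1, 2]]), [0, 1])
        with pytest.raises(ValueError):
            ExhaustiveIGScan().fit(np.zeros((3, 2), dtype=int), [0, 1, 2])

    def test_sklearn_params_round_trip(self):
        est = ExhaustiveIGScan(order=3, alpha=0.1)
        assert est.get_params()["order"] == 3
        est.set_params(order=2)
        assert est.order == 2


# --- stepwise scan ----------------------------------------------------------

class TestStepwiseScan:
    def test_soundness_and_economy(self, multiplicative_dataset):
        g = multiplicative_dataset.genotype_matrix
        sw = StepwiseIGScan(max_order=2, threshold=0.05).fit(
            g.genotypes, g.phenotype
        )
        ex = ExhaustiveIGScan(order=2, keep_all=True).fit(g.genotypes, g.phenotype)
        ex1 = ExhaustiveIGScan(order=1, keep_all=True).fit(g.genotypes, g.phenotype)
        by_idx = {r.snp_indices: r for r in ex.all_results_ + ex1.all_results_}
        for res in sw.results_:
            assert res.ig_bits == pytest.approx(
                by_idx[res.snp_indices].ig_bits, abs=1e-12
            )
        exhaustive_count = g.n_snps + math.comb(g.n_snps, 2)
        assert sw.state_.evaluated_count < exhaustive_count
        assert sw.state_.h_k[1] == len(sw.state_.selected[1])

    def test_threshold_one_degenerates_to_exhaustive(self, planted_pair_matrix):
        g = planted_pair_matrix
        results, state = scan_stepwise(
            g, SearchConfig(max_order=2, threshold=1.0, m_mode="fixed", keep_all=True)
        )
        m = g.n_snps
        assert state.evaluated_per_order[2] == math.comb(m, 2)
        ex = scan_exhaustive(g, order=2, keep_all=True)
        sw_pairs = {r.snp_indices: r for r in results if r.order_k == 2}
        assert len(sw_pairs) == math.comb(m, 2)
        for r in ex:
            assert sw_pairs[r.snp_indices].ig_bits == pytest.approx(
                r.ig_bits, abs=1e-12
            )
            assert sw_pairs[r.snp_indices].p_adjusted == pytest.approx(
                r.p_adjusted, abs=1e-12
            )

    def test_marginal_signal_found_cheaply(self, multiplicative_dataset):
        ds = multiplicative_dataset
        g = ds.genotype_matrix
        results, state = scan_stepwise(g, SearchConfig(max_order=2, threshold=0.05))
        hits = {r.snp_indices for r in results}
        assert tuple(ds.causal_indices) in hits
        assert state.evaluated_count < g.n_snps + math.comb(g.n_snps, 2)

    def test_pure_xor_usually_missed(self):
        # no marginal effects: the forward screen rarely keeps the causal SNPs
        missed = 0
        n_rep = 10
        for r in range(n_rep):
            ds = simulate_case_control(
                builtin_model("xor"), 150, 150, m_noise_snps=28, seed=1000 + r
            )
            g = ds.genotype_matrix
            results, _ = scan_stepwise(g, SearchConfig(max_order=2, threshold=0.05))
            if tuple(ds.causal_indices) not in {r_.snp_indices for r_ in results}:
                missed += 1
        assert missed > n_rep / 2

    def test_three_locus_signal_reached(self, rng):
        # phenotype driven by three SNPs jointly, each with marginal footprint
        n, m = 300, 15
        geno = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
        score = geno[:, [1, 4, 9]].sum(axis=1)
        pheno = (score + rng.normal(0, 1.0, n) > 3.5).astype(np.int8)
        results, state = scan_stepwise(
            GenotypeMatrix(geno, pheno), SearchConfig(max_order=3, threshold=0.05)
        )
        assert state.current_order >= 2
        evaluated_orders = set(state.evaluated_per_order)
        assert 1 in evaluated_orders and 2 in evaluated_orders

    def test_invalid_threshold(self, small_null_matrix):
        with pytest.raises(ValueError):
            scan_stepwise(small_null_matrix, SearchConfig(threshold=0.0))


class TestRanking:
    def test_ties_broken_by_larger_ig(self):
        from igscan.search import InteractionResult

        a = InteractionResult((0,), 1, 0.2, 3, 100, 0.5, 1.0, 2)
        b = InteractionResult((1,), 1, 0.4, 3, 100, 0.5, 1.0, 2)
        ranked = rank_results([a, b])
        assert ranked[0] is b
        assert rank_results([]) == []
        assert rank_results(ranked) == ranked
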