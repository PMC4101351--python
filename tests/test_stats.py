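"""Entropy / information-gain kernel and the gamma-null significance test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from igscan.stats import (
    ContingencyTable,
    bonferroni_adjust,
    conditional_entropy,
    entropy,
    entropy_from_probabilities,
    gamma_null_params,
    ig_pvalue,
    ig_sf,
    information_gain,
)


def naive_entropy(counts):
    """Double-loop oracle, independent of the vectorised implementation."""
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def naive_information_gain(table):
    table = [list(map(float, row)) for row in table]
    n = sum(sum(row) for row in table)
    ncols = len(table[0])
    col = [sum(row[j] for row in table) for j in range(ncols)]
    h_y = naive_entropy(col)
    h_y_x = 0.0
    for row in table:
        tot = sum(row)
        if tot > 0:
            h_y_x += (tot / n) * naive_entropy(row)
    return h_y - h_y_x


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 1), 1.0),
            ((5, 0), 0.0),
            ((1, 3), 0.8112781244591328),  # frozen from the hand oracle
            ((2, 2, 2, 2), 2.0),
        ],
    )
    def test_known_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-12)
        assert entropy(counts) == pytest.approx(naive_entropy(counts), abs=1e-12)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            entropy([0, 0, 0])
        with pytest.raises(ValueError):
            entropy([-1, 2])

    def test_probability_vector_validation(self):
        assert entropy_from_probabilities([0.5, 0.5]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            entropy_from_probabilities([0.5, 0.4])
        with pytest.raises(ValueError):
            entropy_from_probabilities([1.2, -0.2])


class TestConditionalEntropyAndIG:
    def test_independent_table_leaves_hy(self):
        # outer-product table: knowing X says nothing about Y
        t = [[10, 10], [20, 20]]
        assert conditional_entropy(t) == pytest.approx(1.0, abs=1e-12)
        assert information_gain(t) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_table(self):
        t = [[10, 0], [0, 10]]
        assert conditional_entropy(t) == pytest.approx(0.0, abs=1e-12)
        assert information_gain(t) == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_table(self):
        t = [[8, 2], [3, 7]]
        expected_ce = 0.5 * naive_entropy([8, 2]) + 0.5 * naive_entropy([3, 7])
        assert conditional_entropy(t) == pytest.approx(expected_ce, abs=1e-12)
        expected_ig = naive_entropy([11, 9]) - expected_ce
        assert information_gain(t) == pytest.approx(expected_ig, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            information_gain([[0, 0], [0, 0]])

    def test_contingency_table_type(self):
        ct = ContingencyTable(np.array([[8, 2], [3, 7]]))
        assert ct.n_total == 20
        assert ct.levels_x == 2 and ct.levels_y == 2
        assert information_gain(ct) == pytest.approx(
            information_gain([[8, 2], [3, 7]]), abs=1e-15
        )
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -1], [0, 2]]))

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=4),
            min_size=2,
            max_size=9,
        ).filter(
            lambda rows: len({len(r) for r in rows}) == 1
            and sum(map(sum, rows)) > 0
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_ig_bounds_symmetry_and_oracle(self, rows):
        t = np.array(rows, dtype=float)
        ig = information_gain(t)
        assert ig == pytest.approx(naive_information_gain(rows), abs=1e-12)
        # bounds: 0 <= IG <= min(H(X), H(Y))
        assert ig >= 0.0
        assert ig <= entropy(t.sum(axis=1)) + 1e-12
        assert ig <= entropy(t.sum(axis=0)) + 1e-12
        # symmetry: mutual information of the transpose is identical
        assert ig == pytest.approx(information_gain(t.T), abs=1e-12)


class TestGammaNull:
    def test_pair_substitution(self):
        null = gamma_null_params(1000, 9, 2)
        assert null.shape_a == 4.0
        assert null.scale_b == pytest.approx(1.0 / (1000 * math.log(2)), rel=1e-12)

    def test_single_snp_substitution(self):
        null = gamma_null_params(100, 3, 2)
        assert null.shape_a == 1.0
        assert null.scale_b == pytest.approx(1.0 / (100 * math.log(2)), rel=1e-12)

    def test_degenerate_constant_x(self):
        null = gamma_null_params(500, 1, 2)
        assert null.shape_a == 0.0
        assert ig_pvalue(0.3, null) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gamma_null_params(0, 9, 2)
        with pytest.raises(ValueError):
            gamma_null_params(100, 0, 2)

    def test_zero_statistic_and_monotonicity(self):
        null = gamma_null_params(1000, 9, 2)
        assert ig_pvalue(0.0, null) == 1.0
        igs = np.linspace(0, 0.05, 20)
        ps = [ig_pvalue(v, null) for v in igs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        with pytest.raises(ValueError):
            ig_pvalue(-1e-6, null)

    def test_chi_square_identity_spot(self):
        # gamma(df/2, 1/(N ln2)) tail at IG == chi2_df tail at 2 N ln2 IG
        null = gamma_null_params(1000, 9, 2)
        expected = chi2.sf(2 * 1000 * math.log(2) * 0.01, df=8)
        assert ig_pvalue(0.01, null) == pytest.approx(expected, rel=1e-12)

    @given(
        st.integers(min_value=2, max_value=5000),
        st.integers(min_value=2, max_value=27),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=300)
    def test_chi_square_identity_property(self, n, levels_x, ig):
        null = gamma_null_params(n, levels_x, 2)
        df = (levels_x - 1) * (2 - 1)
        oracle = chi2.sf(2.0 * n * math.log(2) * ig, df)
        assert ig_pvalue(ig, null) == pytest.approx(oracle, abs=1e-10)

    def test_vectorised_sf_matches_scalar(self, rng):
        igs = rng.uniform(0, 0.2, size=50)
        ns = rng.integers(10, 2000, size=50)
        lx = rng.integers(1, 10, size=50)
        vec = ig_sf(igs, ns, lx)
        for i in range(50):
            assert vec[i] == pytest.approx(
                ig_pvalue(igs[i], gamma_null_params(int(ns[i]), int(lx[i]))), abs=1e-14
            )


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.001, 50, 0.05), (0.5, 3, 1.0), (1e-8, 499500, 4.995e-3)],
    )
    def test_adjustment(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5, 10)
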