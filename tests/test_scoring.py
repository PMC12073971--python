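"""Msimsc statistic, permutation null, COEs combination and diagnostics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coesnet.scoring import (
    coes_combine,
    group_stats,
    mean_vif,
    msimsc,
    normalize_coes,
    pair_term,
    permutation_test,
    score_genes,
    shapiro_screen,
)


def brute_msimsc(matrix):
    """Oracle: explicit double loop with scalar arithmetic."""
    matrix = np.asarray(matrix, dtype=float)
    total = 0.0
    for i in range(len(matrix)):
        for j in range(i + 1, len(matrix)):
            m1, m2 = matrix[i].mean(), matrix[j].mean()
            d1, d2 = matrix[i].std(ddof=1), matrix[j].std(ddof=1)
            total += (
                0.5 * (d1**2 / d2**2 + d2**2 / d1**2) * ((m1 + m2) / 2.0) ** 2
            )
    return total


class TestGroupStats:
    def test_hand_arithmetic(self):
        (gs,) = group_stats([[2.0, 4.0]])
        assert gs.mu == pytest.approx(3.0)
        assert gs.delta == pytest.approx(math.sqrt(2))
        assert gs.n == 2

    def test_constant_row_has_zero_delta(self):
        (gs,) = group_stats([[5.0, 5.0, 5.0]])
        assert (gs.mu, gs.delta) == (5.0, 0.0)

    def test_nan_row_is_an_error_naming_the_row(self):
        with pytest.raises(ValueError, match="r2"):
            group_stats([[1.0, 2.0], [np.nan, 1.0]], groups=["r1", "r2"])


class TestPairTerm:
    def test_symmetric_case_is_product_of_units(self):
        assert pair_term(1.0, 1.0, 0.7, 0.7) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert pair_term(2.0, 4.0, 1.0, 2.0) == pytest.approx(19.125)

    def test_opposite_means_cancel(self):
        assert pair_term(3.0, -3.0, 1.0, 5.0) == 0.0

    def test_zero_delta_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            pair_term(1.0, 1.0, 0.0, 1.0)


class TestMsimsc:
    def test_two_rows_equal_single_pair_term(self):
        matrix = [[1.0, 2.0, 3.0], [2.0, 5.0, 8.0]]
        result = msimsc(matrix)
        gs = group_stats(matrix)
        assert result.value == pytest.approx(
            pair_term(gs[0].mu, gs[1].mu, gs[0].delta, gs[1].delta)
        )
        assert result.n_pairs == 1

    def test_single_row_is_an_error(self):
        with pytest.raises(ValueError, match="2 rows"):
            msimsc([[1.0, 2.0]])

    @pytest.mark.parametrize("n_rows", list(range(2, 11)))
    def test_matches_brute_force_pair_enumeration(self, n_rows):
        rng = np.random.default_rng(n_rows)
        matrix = rng.normal(size=(n_rows, 6))
        result = msimsc(matrix)
        assert result.value == pytest.approx(brute_msimsc(matrix))
        assert result.n_pairs == n_rows * (n_rows - 1) // 2
        assert result.value == pytest.approx(
            sum(c for _, _, c in result.contributions)
        )


class TestShapiroScreen:
    def test_constant_row_flagged_failed(self):
        report = shapiro_screen([[3.0, 3.0, 3.0, 3.0]])
        assert not report.loc[0, "passed"]
        assert np.isnan(report.loc[0, "w"])

    def test_normal_draws_pass_and_exponential_fail(self):
        rng = np.random.default_rng(42)
        gaussian = rng.normal(size=(1, 50))
        skewed = rng.exponential(size=(1, 50))
        report = shapiro_screen(np.vstack([gaussian, skewed]))
        assert report.loc[0, "passed"]
        assert not report.loc[1, "passed"]

    def test_out_of_range_n_flagged_not_raised(self):
        report = shapiro_screen([[1.0, 2.0]])
        assert not report.loc[0, "passed"]


class TestPermutationTest:
    def test_identical_rows_give_p_one(self):
        matrix = np.tile([1.0, 2.0, 3.0, 4.0], (3, 1))
        result = permutation_test(matrix, n_perm=99, seed=0)
        assert result.p_value == 1.0

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(np.ones((2, 3)), n_perm=0, seed=0)

    def test_planted_group_separation_is_significant(self):
        rng = np.random.default_rng(7)
        means = np.array([0.0, 0.0, 3.0, 3.0])
        matrix = rng.normal(means[:, None], 0.5, size=(4, 10))
        result = permutation_test(matrix, n_perm=999, seed=7)
        assert result.p_value < 0.05

    def test_reproducible_for_fixed_seed(self):
        matrix = np.random.default_rng(1).normal(size=(4, 8))
        a = permutation_test(matrix, n_perm=49, seed=11)
        b = permutation_test(matrix, n_perm=49, seed=11)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_values, b.null_values)


class TestCoesCombine:
    def test_zero_counts_give_zero(self):
        assert coes_combine(0, 123.4, 0, 9.9).m_comb == 0.0

    def test_hand_arithmetic(self):
        assert coes_combine(2, 0.5, 3, 0.2).m_comb == pytest.approx(1.6)

    def test_single_component_identity(self):
        assert coes_combine(1, 0.37, 0, 5.0).m_comb == 0.37

    def test_negative_count_is_an_error(self):
        with pytest.raises(ValueError, match="n_sel"):
            coes_combine(1, 0.5, -1, 0.2)

    @given(
        n_expr=st.integers(0, 50),
        m_expr=st.floats(-100, 100),
        n_sel=st.integers(0, 50),
        m_simsc=st.floats(-100, 100),
    )
    @settings(derandomize=True, max_examples=50)
    def test_exact_linearity(self, n_expr, m_expr, n_sel, m_simsc):
        score = coes_combine(n_expr, m_expr, n_sel, m_simsc)
        assert score.m_comb == n_expr * m_expr + n_sel * m_simsc


class TestNormalizeCoes:
    def test_hand_arithmetic(self):
        scores = normalize_coes({"a": 10.0, "b": 5.0, "c": 0.0})
        assert scores == pytest.approx({"a": 1.0, "b": 0.5, "c": 0.0})

    def test_single_member_cluster(self):
        assert normalize_coes({"only": -3.2}) == {"only": 1.0}

    def test_empty_cluster_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_coes({})

    @given(
        values=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20),
        scale=st.floats(0.01, 100),
        shift=st.floats(-1e3, 1e3),
    )
    @settings(derandomize=True, max_examples=50)
    def test_idempotent_and_affine_invariant(self, values, scale, shift):
        scores = {f"g{i}": v for i, v in enumerate(values)}
        normalized = normalize_coes(scores)
        assert max(normalized.values()) == pytest.approx(1.0)
        again = normalize_coes(normalized)
        assert again == pytest.approx(normalized)
        transformed = normalize_coes(
            {g: scale * v + shift for g, v in scores.items()}
        )
        assert transformed == pytest.approx(normalized, abs=1e-6)


class TestMeanVif:
    def test_orthogonal_design_is_exactly_one(self):
        from scipy.linalg import hadamard

        features = hadamard(8)[:, 1:4].astype(float)
        assert mean_vif(features) == pytest.approx(1.0)

    def test_duplicated_feature_is_capped_with_warning(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 1))
        with pytest.warns(UserWarning, match="collinear"):
            result = mean_vif(np.hstack([x, x, rng.normal(size=(30, 1))]))
        assert result <= 1e6

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        cov = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=80)
        expected = []
        for j in range(3):
            others = np.delete(X, j, axis=1)
            design = np.column_stack([np.ones(len(X)), others])
            beta, *_ = np.linalg.lstsq(design, X[:, j], rcond=None)
            resid = X[:, j] - design @ beta
            r2 = 1 - resid.var() / X[:, j].var()
            expected.append(1.0 / (1.0 - r2))
        assert mean_vif(X) == pytest.approx(np.mean(expected), rel=1e-6)


class TestScoreGenes:
    def test_planted_evidence_ranks_first(self):
        import pandas as pd

        from coesnet.semsim import GeneSimilarityMatrix

        de = pd.DataFrame(
            {"gene": ["a", "b", "c"], "pvalue": [1e-6, 0.5, 0.9]}
        )
        sim = GeneSimilarityMatrix(
            labels=["a", "b", "c"],
            values=np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]]),
        )
        table = score_genes(de, sim, p_cut=0.01, sim_cut=0.5)
        assert table.iloc[0]["gene"] == "a"
        row_a = table.set_index("gene").loc["a"]
        assert row_a["n_expr"] == 1
        assert row_a["n_sel"] == 1
        assert row_a["m_comb"] == pytest.approx(
            1 * (-math.log10(1e-6)) + 1 * 0.9
        )
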