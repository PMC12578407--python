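"""Permutation correlation testing, Fisher ICS meta-analysis, resampling
null and BH adjustment — checked against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hepnet import (
    ExpressionMatrix,
    all_pairs_pvalues,
    bh_fdr,
    fisher_ics,
    meta_edge_table,
    permutation_correlation_pvalue,
    resampling_null_pvalue,
    significant_edges,
)
from hepnet.simulate import ModuleSpec, SyntheticStudySpec, generate_multi_cohort

import pandas as pd


def exhaustive_perm_p(x, y):
    """Brute-force oracle: exact fraction of permutations of y whose |r|
    reaches |r_obs|."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def r(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    r_obs = abs(r(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        hits += abs(r(x, np.array(perm))) >= r_obs - 1e-12
    return hits / total


class TestPermutationP:
    def test_monotone_triplet_matches_enumeration(self):
        # only identity and full reversal of 3 elements reach |r| = 1
        p = permutation_correlation_pvalue([1, 2, 3], [1, 2, 3], exhaustive=True)
        assert p == pytest.approx(2 / 6)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3, 4], [2, 1, 4, 3]),
            ([0.5, 2.0, -1.0, 3.0, 1.0], [1.0, 0.0, 2.0, -1.0, 0.5]),
            ([1, 2, 3, 4, 5, 6], [3, 1, 4, 1.5, 5, 9]),
        ],
    )
    def test_exhaustive_mode_equals_brute_force(self, x, y):
        assert permutation_correlation_pvalue(x, y, exhaustive=True) == pytest.approx(
            exhaustive_perm_p(x, y)
        )

    @pytest.mark.parametrize(
        "x,y",
        [([1, 2, 3, 4, 5], [5, 1, 4, 2, 3]), ([1, 2, 3, 4], [1, 3, 2, 4])],
    )
    def test_add_one_estimator_converges_to_exhaustive(self, x, y):
        exact = exhaustive_perm_p(x, y)
        est = permutation_correlation_pvalue(x, y, n_perm=9999, seed=3)
        assert est == pytest.approx(exact, abs=0.03)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            permutation_correlation_pvalue([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            permutation_correlation_pvalue([1, 2, 3], [1, 2, 3, 4])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_p_always_in_unit_interval_and_never_zero(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        p = permutation_correlation_pvalue(x, y, n_perm=99, seed=seed)
        assert 0 < p <= 1

    def test_spearman_is_rank_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        p1 = permutation_correlation_pvalue(x, y, n_perm=199, seed=1, method="spearman")
        p2 = permutation_correlation_pvalue(np.exp(x), y, n_perm=199, seed=1, method="spearman")
        assert p1 == p2


class TestFisherICS:
    def test_examples(self):
        assert fisher_ics([1, 1, 1]) == 0.0
        assert fisher_ics([math.exp(-1)]) == pytest.approx(2.0)
        # independent evaluation of -2 * sum(ln p)
        assert fisher_ics([0.05, 0.01]) == pytest.approx(
            -2 * (math.log(0.05) + math.log(0.01))
        )

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.1], [-0.2], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            fisher_ics(bad)


class TestResamplingNull:
    def test_zero_ics_has_p_one(self):
        assert resampling_null_pvalue(0.0, [0.2, 0.8, 0.5], k=3, n_resample=100, seed=0) == 1.0

    def test_degenerate_pool_ties_count(self):
        c = 0.3
        ics = -2 * 3 * math.log(c)
        assert resampling_null_pvalue(ics, [c], k=3, n_resample=50, seed=0) == 1.0

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            resampling_null_pvalue(1.0, [], k=2)

    def test_uniform_pool_matches_chi_square_limit(self):
        """With a Uniform(0,1) pool the resampled ICS null is chi-square
        with 2k degrees of freedom (meta p within 0.01 of the analytic
        tail)."""
        from scipy import stats

        rng = np.random.default_rng(42)
        pool = rng.uniform(size=20000)
        k = 3
        for ics_obs in (2.0, 7.0, 12.0):
            p = resampling_null_pvalue(ics_obs, pool, k=k, n_resample=10000, seed=7)
            assert p == pytest.approx(stats.chi2(2 * k).sf(ics_obs), abs=0.01)


class TestBH:
    def bh_oracle(self, p):
        """Literal step-up enumeration: q_(i) = min_{j>=i} min(1, m p_(j)/j)."""
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        for pos, idx in enumerate(order, start=1):
            q[idx] = min(
                min(1.0, m * p[order[j - 1]] / j) for j in range(pos, m + 1)
            )
        return q

    def test_four_element_example(self):
        p = [0.01, 0.04, 0.03, 0.05]
        expected = self.bh_oracle(p)
        assert np.allclose(expected, [0.04, 0.05, 0.05, 0.05])
        assert np.allclose(bh_fdr(p), expected)

    def test_all_equal_and_singleton(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)
        assert np.allclose(bh_fdr([0.123]), [0.123])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(bh_fdr(p), self.bh_oracle(p))

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8), st.data())
    @settings(max_examples=30, deadline=None)
    def test_order_invariance_and_monotonicity(self, p, data):
        q = bh_fdr(p)
        perm = data.draw(st.permutations(range(len(p))))
        q_perm = bh_fdr([p[i] for i in perm])
        assert np.allclose([q_perm[perm.index(i)] for i in range(len(p))], q)
        # raising one raw p never lowers any q
        i = data.draw(st.integers(0, len(p) - 1))
        bumped = list(p)
        bumped[i] = min(1.0, bumped[i] + 0.3)
        assert (np.asarray(bh_fdr(bumped)) >= q - 1e-12).all()

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestAllPairs:
    def test_four_genes_give_six_pairs(self, toy_matrix):
        tab = all_pairs_pvalues(toy_matrix, n_perm=49, seed=0,
                                gene_subset=["G0", "G1", "G2", "G3"])
        assert len(tab) == 6
        assert (tab["gene_a"] < tab["gene_b"]).all()

    def test_repeat_call_is_identical(self, toy_matrix):
        a = all_pairs_pvalues(toy_matrix, n_perm=99, seed=4)
        b = all_pairs_pvalues(toy_matrix, n_perm=99, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_module_attains_minimum_p(self):
        spec = SyntheticStudySpec(
            n_cohorts=1, samples_per_cohort=20,
            modules=(ModuleSpec("M1", 6, 0.9),), n_background_genes=0,
            noise_sd=1e-9, driver_loading=1.0, batch_shift_sd=0.0, seed=3,
        )
        mats, _ = generate_multi_cohort(spec)
        n_perm = 199
        tab = all_pairs_pvalues(mats[0], n_perm=n_perm, seed=0)
        assert (tab["p"] == 1 / (n_perm + 1)).all()

    def test_low_overlap_pairs_are_dropped(self, toy_matrix):
        df = toy_matrix.values.copy()
        df.loc["G0", df.columns[:6]] = np.nan  # only 2 shared obs with anyone
        tab = all_pairs_pvalues(ExpressionMatrix(df, "t"), n_perm=49, seed=0,
                                gene_subset=["G0", "G1", "G2"])
        assert set(zip(tab["gene_a"], tab["gene_b"])) == {("G1", "G2")}


@pytest.fixture(scope="module")
def edge_table(small_study):
    _, matrices, _ = small_study
    return meta_edge_table(matrices, n_perm=199, seed=0, top_var=None,
                           n_resample=2000)


class TestMetaAndEdges:
    def test_table_shape_and_columns(self, edge_table, small_study):
        _, matrices, _ = small_study
        n = matrices[0].n_genes
        assert len(edge_table) == n * (n - 1) // 2
        assert list(edge_table.columns) == [
            "gene_a", "gene_b", "p_cohort_1", "p_cohort_2", "p_cohort_3",
            "ics", "meta_p", "q",
        ]
        pcols = edge_table[["p_cohort_1", "p_cohort_2", "p_cohort_3"]].to_numpy()
        assert np.allclose(edge_table["ics"], -2 * np.log(pcols).sum(axis=1))

    def test_within_module_edges_dominate(self, edge_table, small_study):
        _, _, truth = small_study
        sig = significant_edges(edge_table, 0.05)
        kept = set(zip(sig["gene_a"], sig["gene_b"]))
        m1 = sorted(truth.module_members("M1"))
        within = {(a, b) for i, a in enumerate(m1) for b in m1[i + 1:]}
        assert len(within & kept) / len(within) > 0.9

    def test_significant_edges_thresholds(self, edge_table):
        assert len(significant_edges(edge_table, q_threshold=1.01)) == len(edge_table)
        none = significant_edges(edge_table.assign(q=1.0), q_threshold=0.05)
        assert len(none) == 0

    def test_edges_sorted_by_weight_then_lexicographic(self, edge_table):
        sig = significant_edges(edge_table, 0.05)
        w = sig["weight"].to_numpy()
        assert (np.diff(w) <= 1e-12).all()
        keys = list(zip(-w, sig["gene_a"], sig["gene_b"]))
        assert keys == sorted(keys)
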