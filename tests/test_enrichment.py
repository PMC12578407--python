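"""Hypergeometric annotation, the weighted-KS GSEA engine and the
prognostic-signature status classifier."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hepnet import (
    ExpressionMatrix,
    SignatureDefinition,
    annotate_modules,
    gsea_enrichment_score,
    gsea_significance,
    hypergeometric_tail,
    rank_genes,
    signature_status,
    zscore_log2_housekeeping,
)
from hepnet.network import GeneModule
from hepnet.simulate import plant_signature_response


def brute_force_tail(overlap, set_size, draw_size, universe_size):
    """Exhaustive oracle: enumerate every possible draw of ``draw_size``
    elements from the universe and count those hitting >= overlap of the
    marked set."""
    universe = range(universe_size)
    marked = set(range(set_size))
    hits = total = 0
    for draw in itertools.combinations(universe, draw_size):
        total += 1
        hits += len(marked & set(draw)) >= overlap
    return hits / total


class TestHypergeometricTail:
    @pytest.mark.parametrize(
        "overlap,set_size,draw,universe",
        [(3, 5, 3, 10), (2, 4, 6, 12), (1, 3, 3, 9), (4, 6, 5, 11), (0, 5, 3, 10)],
    )
    def test_matches_exhaustive_enumeration(self, overlap, set_size, draw, universe):
        assert hypergeometric_tail(overlap, set_size, draw, universe) == pytest.approx(
            brute_force_tail(overlap, set_size, draw, universe)
        )

    def test_trivial_cases(self):
        assert hypergeometric_tail(0, 5, 3, 10) == 1.0
        assert hypergeometric_tail(3, 10, 3, 10) == pytest.approx(1.0)  # set = universe

    def test_inconsistent_counts_are_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(4, 3, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_tail(1, 11, 3, 10)


class TestAnnotateModules:
    def test_disjoint_module_has_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        module = GeneModule("m", frozenset(universe[:5]), 1.0, float("nan"))
        sets = [("S1", "", universe[10:15]), ("S2", "", universe[15:20])]
        table = annotate_modules([module], sets, universe)
        assert (table["p"] == 1.0).all()

    def test_module_identical_to_set_is_most_extreme(self):
        universe = [f"g{i}" for i in range(12)]
        members = universe[:4]
        module = GeneModule("m", frozenset(members), 1.0, float("nan"))
        table = annotate_modules([module], [("S", "", members)], universe)
        assert table.loc[0, "p"] == pytest.approx(1 / math.comb(12, 4))

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            annotate_modules([], [("S", "", ["a"])], [])


class TestRankGenes:
    def test_identical_matrices_give_zero_scores_in_gene_order(self, toy_matrix):
        ranked = rank_genes(toy_matrix, toy_matrix)
        assert (ranked.to_numpy() == 0).all()
        assert list(ranked.index) == sorted(toy_matrix.gene_ids)

    def test_single_raised_gene_ranks_first(self, toy_matrix):
        bumped = toy_matrix.values.copy()
        bumped.loc["G3"] += 2.0
        ranked = rank_genes(ExpressionMatrix(bumped, "t"), toy_matrix)
        assert ranked.index[0] == "G3"
        assert ranked.iloc[0] == pytest.approx(2.0)

    @given(st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_common_per_sample_shift(self, shift):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(10)]
        t = pd.DataFrame(rng.normal(size=(10, 6)), index=genes)
        r = pd.DataFrame(rng.normal(size=(10, 6)), index=genes)
        base = rank_genes(ExpressionMatrix(t.copy()), ExpressionMatrix(r))
        shifted = rank_genes(ExpressionMatrix(t + shift), ExpressionMatrix(r + shift))
        assert list(base.index) == list(shifted.index)
        assert np.allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-9)

    def test_no_shared_genes_is_an_error(self, toy_matrix):
        other = ExpressionMatrix(
            toy_matrix.values.copy().set_axis([f"X{i}" for i in range(6)]), "o"
        )
        with pytest.raises(ValueError):
            rank_genes(toy_matrix, other)


def hand_running_sum(ranked, gene_set, w=1.0):
    """Independent step-by-step running-sum tabulation."""
    hits = [g in gene_set for g in ranked.index]
    total = sum(abs(s) ** w for s, h in zip(ranked.to_numpy(), hits) if h)
    n_miss = len(ranked) - sum(hits)
    run, out = 0.0, []
    for s, h in zip(ranked.to_numpy(), hits):
        run += (abs(s) ** w) / total if h else -1.0 / n_miss
        out.append(run)
    return out


class TestEnrichmentScore:
    scores = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0, -3.0],
                       index=["g1", "g2", "g3", "g4", "g5", "g6"])

    def test_top_gene_set_scores_one(self):
        es, _ = gsea_enrichment_score(self.scores, {"g1"})
        assert es == pytest.approx(1.0)

    def test_bottom_gene_set_scores_minus_one(self):
        es, _ = gsea_enrichment_score(self.scores, {"g6"})
        assert es == pytest.approx(-1.0)

    def test_six_gene_toy_matches_hand_enumeration(self):
        gene_set = {"g1", "g3"}
        es, running = gsea_enrichment_score(self.scores, gene_set)
        expected = hand_running_sum(self.scores, gene_set)
        assert np.allclose(running, expected)
        assert es == pytest.approx(max(expected, key=abs))

    def test_weight_zero_equals_classical_ks(self):
        gene_set = {"g2", "g5", "g6"}
        es, _ = gsea_enrichment_score(self.scores, gene_set, weight_exponent=0)
        # direct KS statistic: max deviation between hit and miss ECDFs
        hits = np.array([g in gene_set for g in self.scores.index])
        dev = np.cumsum(np.where(hits, 1 / hits.sum(), -1 / (~hits).sum()))
        assert es == pytest.approx(dev[np.argmax(np.abs(dev))])

    def test_matches_independent_gsea_implementation(self):
        """Cross-check the weighted-KS ES against gseapy's prerank engine."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(7)
        genes = [f"G{i:02d}" for i in range(40)]
        scores = np.sort(rng.normal(size=40))[::-1]
        ranked = pd.Series(scores, index=genes)
        gene_set = list(rng.choice(genes, size=8, replace=False))
        res = gseapy.prerank(
            rnk=ranked.reset_index(), gene_sets={"S": gene_set},
            permutation_num=10, min_size=1, max_size=50, seed=1,
            outdir=None, no_plot=True,
        )
        es, _ = gsea_enrichment_score(ranked, set(gene_set))
        assert es == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_es_bounded_and_running_sum_terminates_at_zero(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        ranked = pd.Series(
            np.sort(rng.normal(size=n))[::-1], index=[f"G{i}" for i in range(n)]
        )
        size = int(rng.integers(1, n))
        gene_set = set(rng.choice(ranked.index, size=size, replace=False))
        es, running = gsea_enrichment_score(ranked, gene_set)
        assert -1.0 <= es <= 1.0
        assert running[-1] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_sets_are_errors(self):
        with pytest.raises(ValueError):
            gsea_enrichment_score(self.scores, {"absent"})
        with pytest.raises(ValueError):
            gsea_enrichment_score(self.scores, set(self.scores.index))


def _group_matrices(seed, n_genes=60, n_per_group=10, shift_genes=(), delta=0.0):
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    t = pd.DataFrame(rng.normal(size=(n_genes, n_per_group)), index=genes,
                     columns=[f"T{j}" for j in range(n_per_group)])
    r = pd.DataFrame(rng.normal(size=(n_genes, n_per_group)), index=genes,
                     columns=[f"R{j}" for j in range(n_per_group)])
    if shift_genes:
        t.loc[list(shift_genes)] += delta
    return ExpressionMatrix(t, "test"), ExpressionMatrix(r, "ref"), genes


class TestGseaSignificance:
    def test_identical_matrices_are_null(self, toy_matrix):
        res = gsea_significance(toy_matrix, toy_matrix, [("S", {"G0", "G1"})],
                                n_perm=50, seed=0)
        assert res[0].p == 1.0
        assert res[0].es == pytest.approx(0.0)

    def test_planted_shift_is_detected_as_induced(self):
        shift = [f"G{i:03d}" for i in range(15)]
        test, ref, _ = _group_matrices(3, shift_genes=shift, delta=2.0)
        res = gsea_significance(test, ref, [("S", set(shift))], n_perm=199, seed=1)
        assert res[0].direction == "induced"
        assert res[0].q < 0.05
        assert res[0].nes > 1.0

    def test_null_pvalues_are_uniform(self):
        """Test and reference drawn from the same distribution: the
        fraction of p <= 0.05 stays inside the binomial 99% CI of 0.05
        over 150 seeded set tests."""
        import math

        sets = [("A", None), ("B", None), ("C", None)]
        n_tests = n_le = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            test, ref, genes = _group_matrices(seed, n_genes=60, n_per_group=10)
            gene_sets = [
                (name, set(rng.choice(genes, 10, replace=False))) for name, _ in sets
            ]
            for res in gsea_significance(test, ref, gene_sets, n_perm=199, seed=seed):
                n_tests += 1
                n_le += res.p <= 0.05
        half = 2.5758 * math.sqrt(0.05 * 0.95 / n_tests)
        assert abs(n_le / n_tests - 0.05) <= half

    def test_gene_set_permutation_fallback_for_tiny_groups(self):
        test, ref, genes = _group_matrices(4, n_per_group=2)
        res = gsea_significance(test, ref, [("S", set(genes[:10]))], n_perm=99, seed=2)
        assert 0 < res[0].p <= 1

    def test_too_few_permutations_is_an_error(self, toy_matrix):
        with pytest.raises(ValueError):
            gsea_significance(toy_matrix, toy_matrix, [("S", {"G0"})], n_perm=5)


class TestSignatureStatus:
    sig = SignatureDefinition(
        "pls",
        frozenset(f"G{i:03d}" for i in range(10)),
        frozenset(f"G{i:03d}" for i in range(10, 20)),
    )

    def test_identical_matrices_call_intermediate(self):
        test, _, _ = _group_matrices(0)
        status = signature_status(test, test, self.sig, n_perm=99, seed=0)
        assert status.call == "intermediate"

    def test_planted_injury_calls_poor_and_reversal_calls_good(self):
        test, ref, _ = _group_matrices(1, n_per_group=20)
        labels = ["injured"] * test.n_samples
        injured = plant_signature_response(test, self.sig, labels, 2.0)
        st_poor = signature_status(injured, ref, self.sig, n_perm=199, seed=3)
        assert st_poor.call == "poor"
        reverted = plant_signature_response(injured, self.sig, labels, -4.0)
        st_good = signature_status(reverted, ref, self.sig, n_perm=199, seed=3)
        assert st_good.call == "good"

    def test_calls_are_antisymmetric_under_sign_swap(self):
        test, ref, _ = _group_matrices(2, n_per_group=20)
        labels = ["injured"] * test.n_samples
        plus = plant_signature_response(test, self.sig, labels, 2.0)
        minus = plant_signature_response(test, self.sig, labels, -2.0)
        call_plus = signature_status(plus, ref, self.sig, n_perm=199, seed=5).call
        call_minus = signature_status(minus, ref, self.sig, n_perm=199, seed=5).call
        assert (call_plus, call_minus) == ("poor", "good")

    def test_unmeasured_subset_is_an_error(self):
        test, ref, _ = _group_matrices(0)
        sig = SignatureDefinition("x", frozenset({"ZZZ"}), frozenset({"G000"}))
        with pytest.raises(ValueError):
            signature_status(test, ref, sig, n_perm=99)


class TestZscoreHousekeeping:
    def test_rows_have_zero_mean_unit_sd(self, toy_matrix):
        out = zscore_log2_housekeeping(toy_matrix, ["G0", "G1"])
        vals = out.values.to_numpy()
        assert np.allclose(vals.mean(axis=1), 0.0, atol=1e-12)
        sds = vals.std(axis=1)
        assert np.allclose(sds[sds > 0], 1.0)

    def test_per_sample_shift_is_absorbed(self, toy_matrix):
        shifted = toy_matrix.values.copy()
        shifted.iloc[:, 2] += 7.5
        out1 = zscore_log2_housekeeping(toy_matrix, ["G0", "G1"])
        out2 = zscore_log2_housekeeping(ExpressionMatrix(shifted, "t"), ["G0", "G1"])
        assert np.allclose(out1.values.to_numpy(), out2.values.to_numpy(), atol=1e-9)

    def test_constant_gene_becomes_zeros_not_error(self, toy_matrix):
        df = toy_matrix.values.copy()
        hk = ["G0", "G1"]
        # constant after housekeeping normalization
        df.loc["G5"] = df.loc[hk].mean(axis=0) + 1.0
        out = zscore_log2_housekeeping(ExpressionMatrix(df, "t"), hk)
        assert (out.values.loc["G5"] == 0).all()

    def test_empty_housekeeping_is_an_error(self, toy_matrix):
        with pytest.raises(ValueError):
            zscore_log2_housekeeping(toy_matrix, [])
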