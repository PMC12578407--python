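"""Planted-truth simulation studies for the pipeline's operating
characteristics.

Each study regenerates synthetic multi-cohort data under the package's
reference conditions (3 cohorts x 80 samples; modules of 12/16/20 genes at
within-module correlation 0.6 and driver loading 0.9; 50 background genes),
runs the relevant pipeline stages, and scores the result against the
planted truth: edge-filter sensitivity/specificity, module-recovery ARI,
driver top-2 recovery, signature-status call rates, and the null
calibration of the permutation and resampling machinery.

Study loops use 300 permutations per pair and 4,000 resampling draws — a
deliberate simulation scale; single analyses default to the pipeline's
1,000 / 10,000.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .coexpr import meta_edge_table, significant_edges, sample_null_ics, permutation_correlation_pvalue
from .drivers import key_driver_analysis
from .enrichment import signature_status
from .expression import ExpressionMatrix
from .network import build_pmfg, detect_modules_multiscale
from .simulate import (
    SyntheticStudySpec,
    default_signature_from_background,
    default_study_spec,
    generate_multi_cohort,
    plant_signature_response,
)

__all__ = [
    "recovery_study",
    "signature_call_study",
    "null_pvalue_calibration",
    "ics_null_ks",
]

STUDY_N_PERM = 300
STUDY_N_RESAMPLE = 4000


def _run_discovery(spec: SyntheticStudySpec, n_perm: int, n_resample: int,
                   edge_fdr: float = 0.05, min_size: int = 10, n_max: int = 5):
    matrices, truth = generate_multi_cohort(spec)
    edges = meta_edge_table(
        matrices, n_perm=n_perm, seed=spec.seed, top_var=None, n_resample=n_resample
    )
    sig = significant_edges(edges, edge_fdr)
    nodes = sorted(set(sig["gene_a"]) | set(sig["gene_b"]))
    net = build_pmfg(sig.itertuples(index=False, name=None), nodes) if nodes else None
    return matrices, truth, edges, sig, net


def _edge_metrics(truth, edges, sig) -> tuple[float, float]:
    """(within-module sensitivity, module-to-background rejection rate)."""
    assign = truth.module_assignment
    kept = {tuple(sorted(p)) for p in zip(sig["gene_a"], sig["gene_b"])}
    n_within = hit_within = n_cross = kept_cross = 0
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        ma, mb = assign[a], assign[b]
        pair = tuple(sorted((a, b)))
        if ma == mb and ma != "background":
            n_within += 1
            hit_within += pair in kept
        elif "background" in (ma, mb) and ma != mb:
            n_cross += 1
            kept_cross += pair in kept
    sens = hit_within / n_within if n_within else float("nan")
    rej = 1 - kept_cross / n_cross if n_cross else float("nan")
    return sens, rej


def _module_ari(truth, net, min_size: int, scale: float = 1.0) -> float:
    modules = detect_modules_multiscale(net, scales=[scale], min_size=min_size)
    label_of = {}
    for m in modules:
        for g in m.members:
            label_of[g] = m.module_id
    planted = [g for g, mod in truth.module_assignment.items() if mod != "background"]
    true_labels = [truth.module_assignment[g] for g in planted]
    pred_labels = [label_of.get(g, "none") for g in planted]
    return float(adjusted_rand_score(true_labels, pred_labels))


def _driver_top2(truth, net, min_size: int, n_max: int, scale: float = 1.0) -> float:
    """Fraction of planted modules whose driver ranks top-2 in the detected
    module that best overlaps it."""
    modules = detect_modules_multiscale(net, scales=[scale], min_size=min_size)
    if not modules:
        return 0.0
    n_ok = 0
    planted_ids = sorted(truth.driver_genes)
    for mid in planted_ids:
        members = set(truth.module_members(mid))
        best = max(modules, key=lambda m: len(m.members & members))
        if not (best.members & members):
            continue
        results = key_driver_analysis(net, best, n_max=n_max)
        top2 = {r.gene for r in results if r.rank <= 2}
        if set(truth.driver_genes[mid]) & top2:
            n_ok += 1
    return n_ok / len(planted_ids)


def recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_perm: int = STUDY_N_PERM,
    n_resample: int = STUDY_N_RESAMPLE,
    edge_fdr: float = 0.05,
    min_size: int = 10,
    n_max: int = 5,
    spec_overrides: dict | None = None,
) -> dict:
    """Edge, module and driver recovery over seeded replicates of the
    reference study.

    Returns mean within-module edge sensitivity, mean module-to-background
    rejection rate, mean module-recovery ARI (resolution 1.0), and the
    fraction of (seed, module) replicates whose planted driver ranks top-2.
    """
    sens, rej, aris, top2 = [], [], [], []
    for i in range(n_seeds):
        spec = default_study_spec(seed=base_seed + i, **(spec_overrides or {}))
        _, truth, edges, sig, net = _run_discovery(
            spec, n_perm, n_resample, edge_fdr, min_size, n_max
        )
        s, r = _edge_metrics(truth, edges, sig)
        sens.append(s)
        rej.append(r)
        if net is None or net.graph.number_of_edges() == 0:
            aris.append(0.0)
            top2.append(0.0)
            continue
        aris.append(_module_ari(truth, net, min_size))
        top2.append(_driver_top2(truth, net, min_size, n_max))
    return {
        "n_seeds": n_seeds,
        "edge_sensitivity": float(np.mean(sens)),
        "background_rejection": float(np.mean(rej)),
        "module_ari": float(np.mean(aris)),
        "module_ari_min": float(np.min(aris)),
        "driver_top2_rate": float(np.mean(top2)),
    }


def signature_call_study(
    n_seeds: int = 40,
    base_seed: int = 0,
    delta: float = 2.0,
    n_genes: int = 100,
    n_signature: int = 20,
    n_per_group: int = 20,
    noise_sd: float = 1.0,
    n_perm: int = 200,
    fdr_cut: float = 0.25,
) -> dict:
    """Signature-status call rates on planted injury/reversal comparisons.

    Per seed, a flat matrix of ``n_genes`` i.i.d. N(0, noise_sd) genes over
    2 * ``n_per_group`` samples is drawn; the first ``n_signature`` genes
    form the poor subset and the next the good subset. Four comparisons are
    scored: planted injury (+delta poor / -delta good on the test group),
    its reversal applied on top of the injured matrix, the sign-swapped
    plant, and test = reference.
    """
    import pandas as pd
    from .simulate import SignatureDefinition

    genes = [f"G{i:03d}" for i in range(n_genes)]
    sig = SignatureDefinition(
        "study", frozenset(genes[:n_signature]), frozenset(genes[n_signature: 2 * n_signature])
    )
    counts = {"poor": 0, "good": 0, "reversal_good": 0, "null_intermediate": 0,
              "swap_good": 0}
    for i in range(n_seeds):
        rng = np.random.default_rng([base_seed, i])
        cols = [f"S{j}" for j in range(2 * n_per_group)]
        base = pd.DataFrame(rng.normal(0.0, noise_sd, (n_genes, 2 * n_per_group)),
                            index=genes, columns=cols)
        ref = ExpressionMatrix(base.iloc[:, n_per_group:].copy(), "ref")
        test0 = ExpressionMatrix(base.iloc[:, :n_per_group].copy(), "test")
        labels = ["injured"] * n_per_group

        injured = plant_signature_response(test0, sig, labels, delta)
        st = signature_status(injured, ref, sig, n_perm=n_perm, seed=base_seed + i,
                              fdr_cut=fdr_cut)
        counts["poor"] += st.call == "poor"

        reverted = plant_signature_response(injured, sig, labels, -2 * delta)
        st = signature_status(reverted, ref, sig, n_perm=n_perm, seed=base_seed + i,
                              fdr_cut=fdr_cut)
        counts["reversal_good"] += st.call == "good"

        swapped = plant_signature_response(test0, sig, labels, -delta)
        st = signature_status(swapped, ref, sig, n_perm=n_perm, seed=base_seed + i,
                              fdr_cut=fdr_cut)
        counts["swap_good"] += st.call == "good"

        st = signature_status(test0, test0, sig, n_perm=n_perm, seed=base_seed + i,
                              fdr_cut=fdr_cut)
        counts["null_intermediate"] += st.call == "intermediate"

    return {
        "n_seeds": n_seeds,
        "poor_call_rate": counts["poor"] / n_seeds,
        "reversal_good_rate": counts["reversal_good"] / n_seeds,
        "swap_good_rate": counts["swap_good"] / n_seeds,
        "null_intermediate_rate": counts["null_intermediate"] / n_seeds,
    }


def null_pvalue_calibration(
    n_pairs: int = 2000,
    n_obs: int = 30,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of null permutation p-values at or below alpha for
    independent standard-normal gene pairs (expected: alpha)."""
    rng = np.random.default_rng(seed)
    n_le = 0
    for i in range(n_pairs):
        x = rng.standard_normal(n_obs)
        y = rng.standard_normal(n_obs)
        p = permutation_correlation_pvalue(x, y, n_perm=n_perm, seed=int(rng.integers(2**31)))
        n_le += p <= alpha
    return {"n_pairs": n_pairs, "fraction_le_alpha": n_le / n_pairs, "alpha": alpha}


def ics_null_ks(
    k: int = 3,
    n_resample: int = 10000,
    pool_size: int = 50000,
    seed: int = 0,
) -> dict:
    """KS distance between the resampled ICS null (Uniform(0,1) pool) and
    its analytic chi-square(2k) limit."""
    rng = np.random.default_rng(seed)
    pool = rng.uniform(0.0, 1.0, pool_size)
    null = sample_null_ics(pool, k, n_resample, int(rng.integers(2**31)))
    d = float(stats.kstest(null, stats.chi2(df=2 * k).cdf).statistic)
    return {"k": k, "n_resample": n_resample, "ks_d": d}
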