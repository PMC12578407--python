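"""Gene-set annotation, GSEA engine, and prognostic-signature status calls.

Three layers:

* hypergeometric over-representation of gene sets in network modules
  (exact upper-tail, BH-adjusted across all module x set tests);
* a weighted Kolmogorov-Smirnov GSEA engine — genes are ranked by the
  difference of group means on log2 scale, the running sum increments by
  normalized |score|^w at set hits and decrements by 1/(N - N_hit) at
  misses, significance comes from sample-label permutations (gene-set
  permutation as a logged fallback for tiny groups) with a sign-matched
  NES;
* the signature-status classifier: GSEA of the poor- and good-prognosis
  subsets of a prognostic signature versus a reference condition, combined
  into a categorical poor/intermediate/good call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .simulate import SignatureDefinition

__all__ = [
    "EnrichmentResult",
    "SignatureStatus",
    "hypergeometric_tail",
    "annotate_modules",
    "rank_genes",
    "gsea_enrichment_score",
    "gsea_significance",
    "signature_status",
    "zscore_log2_housekeeping",
]

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class EnrichmentResult:
    """GSEA outcome for one gene set versus one comparison."""

    gene_set: str
    es: float
    nes: float
    p: float
    q: float
    direction: str  # "induced" iff es > 0 else "suppressed"


@dataclass(frozen=True)
class SignatureStatus:
    poor_result: EnrichmentResult
    good_result: EnrichmentResult
    call: str  # poor | intermediate | good


def hypergeometric_tail(overlap: int, set_size: int, draw_size: int, universe_size: int) -> float:
    """Exact upper-tail P(X >= overlap), X ~ Hypergeom(universe, set, draw)."""
    if min(overlap, set_size, draw_size, universe_size) < 0:
        raise ValueError("counts must be non-negative")
    if set_size > universe_size or draw_size > universe_size:
        raise ValueError("set and draw sizes cannot exceed the universe")
    if overlap > min(set_size, draw_size):
        raise ValueError("overlap exceeds set or draw size")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, draw_size))


def annotate_modules(modules, collections, universe) -> pd.DataFrame:
    """Hypergeometric annotation of modules against a gene-set collection.

    ``collections`` holds GMT-style ``(name, description, members)``
    triples. Gene sets are intersected with the universe before testing.
    Returns one row per (module, gene set) with overlap, p and BH q across
    all tests, sorted by q then p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    collections = list(collections)
    if not collections:
        raise ValueError("empty gene-set collection")
    rows = []
    for module in modules:
        members = set(module.members) & universe
        for name, _desc, genes in collections:
            gset = set(genes) & universe
            if not gset:
                continue
            overlap = len(members & gset)
            p = hypergeometric_tail(overlap, len(gset), len(members), len(universe))
            rows.append(
                {
                    "module_id": module.module_id,
                    "gene_set": name,
                    "module_size": len(members),
                    "set_size": len(gset),
                    "overlap": overlap,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        from .coexpr import bh_fdr

        out["q"] = bh_fdr(out["p"])
        out = out.sort_values(["q", "p", "module_id", "gene_set"]).reset_index(drop=True)
    return out


def _rank_order(scores: pd.Series) -> pd.Series:
    """Descending score, ascending gene id on ties (deterministic)."""
    df = pd.DataFrame({"score": scores.to_numpy(), "gene": scores.index.astype(str)})
    df = df.sort_values(["score", "gene"], ascending=[False, True])
    return pd.Series(df["score"].to_numpy(), index=df["gene"].to_numpy())


def rank_genes(
    test: ExpressionMatrix,
    reference: ExpressionMatrix,
    metric: str = "mean_diff",
) -> pd.Series:
    """Rank shared genes by differential expression of test vs reference.

    Default metric is the difference of group means on log2 scale;
    ``"signal_to_noise"`` divides by the summed group standard deviations
    (floored GSEA-style at 0.2 of the absolute mean). Returns an ordered
    Series (descending score, gene-id tie-break).
    """
    shared = sorted(set(test.gene_ids) & set(reference.gene_ids))
    if not shared:
        raise ValueError("no shared genes between test and reference")
    t = test.values.loc[shared]
    r = reference.values.loc[shared]
    diff = t.mean(axis=1) - r.mean(axis=1)
    if metric == "mean_diff":
        scores = diff
    elif metric == "signal_to_noise":
        sd = t.std(axis=1, ddof=1).fillna(0.0) + r.std(axis=1, ddof=1).fillna(0.0)
        floor = 0.2 * (t.mean(axis=1).abs() + r.mean(axis=1).abs()) / 2 + 1e-12
        scores = diff / np.maximum(sd, floor)
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    return _rank_order(scores)


def gsea_enrichment_score(ranked: pd.Series, gene_set, weight_exponent: float = 1.0):
    """Weighted KS enrichment score over a ranked gene list.

    Hits increment the running sum by |score|^weight_exponent normalized
    over the in-set total (equal hit weights when that total is zero, and
    always when weight_exponent = 0, the classical KS case); misses
    decrement by 1/(N - N_hit). The running sum starts at 0 before the
    first gene and returns to 0 after the last; es is the signed extreme
    deviation.
    """
    genes = np.asarray(ranked.index, dtype=object)
    scores = ranked.to_numpy(dtype=float)
    gene_set = set(gene_set)
    hit = np.fromiter((g in gene_set for g in genes), dtype=bool, count=genes.size)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == genes.size:
        raise ValueError("gene set equals the full ranked universe")

    w = np.zeros(genes.size)
    if weight_exponent == 0:
        w[hit] = 1.0
    else:
        w[hit] = np.abs(scores[hit]) ** weight_exponent
    total = w.sum()
    if total <= 0:
        w[hit] = 1.0
        total = float(n_hit)
    steps = np.where(hit, w / total, -1.0 / (genes.size - n_hit))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_for_order(order_scores: np.ndarray, hit: np.ndarray, weight_exponent: float) -> float:
    """ES on pre-ordered arrays (fast path for permutation nulls)."""
    n = hit.size
    n_hit = int(hit.sum())
    w = np.zeros(n)
    if weight_exponent == 0:
        w[hit] = 1.0
    else:
        w[hit] = np.abs(order_scores[hit]) ** weight_exponent
    total = w.sum()
    if total <= 0:
        w[hit] = 1.0
        total = float(n_hit)
    steps = np.where(hit, w / total, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_significance(
    test: ExpressionMatrix,
    reference: ExpressionMatrix,
    gene_sets,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    metric: str = "mean_diff",
) -> list[EnrichmentResult]:
    """GSEA with permutation significance for a list of gene sets.

    ``gene_sets`` holds ``(name, members)`` pairs (or GMT triples). With at
    least 3 samples per group the null ranks come from sample-label
    permutations; otherwise gene-set permutation is used and logged. Per
    set: add-one empirical p of |es| within the matching-sign null subset
    (ties count), NES = es / mean(|null es| of matching sign), BH q across
    sets, direction from the sign of es.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    pairs = []
    for entry in gene_sets:
        if len(entry) == 3:
            name, _desc, members = entry
        else:
            name, members = entry
        pairs.append((str(name), set(members)))
    if not pairs:
        raise ValueError("no gene sets supplied")

    shared = sorted(set(test.gene_ids) & set(reference.gene_ids))
    ranked = rank_genes(test, reference, metric=metric)
    if not ranked.to_numpy().any():
        # fully degenerate comparison: no expression difference anywhere, so
        # the tie-broken ranking carries no signal and no set is enriched
        logger.info("all ranking scores are zero; returning null enrichment")
        return [
            EnrichmentResult(gene_set=name, es=0.0, nes=0.0, p=1.0, q=1.0,
                             direction="suppressed")
            for name, _members in pairs
        ]
    observed = {name: gsea_enrichment_score(ranked, members, weight_exponent)[0]
                for name, members in pairs}

    rng = np.random.default_rng(seed)
    sample_perm = test.n_samples >= 3 and reference.n_samples >= 3
    null_es = {name: np.empty(n_perm) for name, _ in pairs}

    if sample_perm:
        t = test.values.loc[shared].to_numpy(dtype=float)
        r = reference.values.loc[shared].to_numpy(dtype=float)
        combined = np.hstack([t, r])
        n_t = t.shape[1]
        gene_arr = np.asarray(shared, dtype=object)
        for b in range(n_perm):
            cols = rng.permutation(combined.shape[1])
            diff = combined[:, cols[:n_t]].mean(axis=1) - combined[:, cols[n_t:]].mean(axis=1)
            order = np.lexsort((gene_arr, -diff))
            og = gene_arr[order]
            osc = diff[order]
            for name, members in pairs:
                hit = np.fromiter((g in members for g in og), dtype=bool, count=og.size)
                null_es[name][b] = _es_for_order(osc, hit, weight_exponent)
    else:
        logger.info("fewer than 3 samples per group: gene-set permutation null")
        gene_arr = np.asarray(ranked.index, dtype=object)
        osc = ranked.to_numpy(dtype=float)
        n = gene_arr.size
        for name, members in pairs:
            size = len(members & set(shared))
            for b in range(n_perm):
                idx = rng.choice(n, size=size, replace=False)
                hit = np.zeros(n, dtype=bool)
                hit[idx] = True
                null_es[name][b] = _es_for_order(osc, hit, weight_exponent)

    raw = []
    for name, _members in pairs:
        es = observed[name]
        null = null_es[name]
        sign = 1.0 if es > 0 else -1.0
        # empirical p within the matching-sign null subset (standard GSEA
        # convention; keeps null p uniform rather than stacked below 0.5)
        same_sign = null[np.sign(null) == sign]
        exceed = int((np.abs(same_sign) >= abs(es) - _TIE_EPS).sum())
        p = (1 + exceed) / (same_sign.size + 1)
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        raw.append((name, es, nes, p))

    from .coexpr import bh_fdr

    qs = bh_fdr([rec[3] for rec in raw])
    return [
        EnrichmentResult(
            gene_set=name,
            es=es,
            nes=nes,
            p=p,
            q=float(q),
            direction="induced" if es > 0 else "suppressed",
        )
        for (name, es, nes, p), q in zip(raw, qs)
    ]


def signature_status(
    test: ExpressionMatrix,
    reference: ExpressionMatrix,
    signature: SignatureDefinition,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_cut: float = 0.25,
    weight_exponent: float = 1.0,
) -> SignatureStatus:
    """Classify a comparison as poor / intermediate / good prognosis.

    Runs GSEA for the signature's poor and good subsets (test vs
    reference). The call is "poor" when the poor subset is induced or the
    good subset suppressed below ``fdr_cut`` and no converse evidence
    exists; "good" for the mirror image; "intermediate" otherwise
    (conflicting double-significant calls are logged and resolve to
    intermediate).
    """
    shared = set(test.gene_ids) & set(reference.gene_ids)
    if not (signature.poor_genes & shared):
        raise ValueError("poor-prognosis subset entirely unmeasured")
    if not (signature.good_genes & shared):
        raise ValueError("good-prognosis subset entirely unmeasured")
    poor_res, good_res = gsea_significance(
        test,
        reference,
        [("poor", signature.poor_genes), ("good", signature.good_genes)],
        n_perm=n_perm,
        seed=seed,
        weight_exponent=weight_exponent,
    )
    poor_evidence = (poor_res.direction == "induced" and poor_res.q < fdr_cut) or (
        good_res.direction == "suppressed" and good_res.q < fdr_cut
    )
    good_evidence = (poor_res.direction == "suppressed" and poor_res.q < fdr_cut) or (
        good_res.direction == "induced" and good_res.q < fdr_cut
    )
    if poor_evidence and good_evidence:
        logger.warning(
            "conflicting signature enrichment (poor %s q=%.3g, good %s q=%.3g); "
            "calling intermediate",
            poor_res.direction, poor_res.q, good_res.direction, good_res.q,
        )
        call = "intermediate"
    elif poor_evidence:
        call = "poor"
    elif good_evidence:
        call = "good"
    else:
        call = "intermediate"
    return SignatureStatus(poor_res, good_res, call)


def zscore_log2_housekeeping(matrix: ExpressionMatrix, housekeeping) -> ExpressionMatrix:
    """Housekeeping-normalized z-scores of log2 expression.

    Per sample, the mean of the housekeeping genes is subtracted (so any
    per-sample additive shift cancels); each gene row is then z-scored
    across samples. Constant rows map to all zeros with a logged warning.
    """
    housekeeping = list(housekeeping)
    if not housekeeping:
        raise ValueError("empty housekeeping list")
    missing = [g for g in housekeeping if g not in matrix.values.index]
    if missing:
        raise KeyError(f"housekeeping gene(s) absent: {missing[:5]}")
    df = matrix.values.copy()
    df = df - df.loc[housekeeping].mean(axis=0)
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant gene row(s) mapped to zeros after normalization",
            int(constant.sum()),
        )
    sd = sd.replace(0.0, 1.0)
    out = df.sub(mean, axis=0).div(sd, axis=0)
    out.loc[constant.to_numpy()] = 0.0
    return ExpressionMatrix(out, matrix.cohort_id)
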