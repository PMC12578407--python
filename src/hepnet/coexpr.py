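"""Per-cohort permutation correlation testing and cross-cohort meta-analysis.

For every gene pair, each cohort contributes a two-sided empirical p-value
for the Pearson correlation, obtained by permuting one vector (add-one
estimator, so p is never 0). The per-cohort nominal p-values are combined
with Fisher's inverse chi-square statistic, ICS = -2 * sum(ln p), whose
significance is evaluated against an empirical null built by iteratively
resampling nominal p-values from the observed pool; the resulting meta
p-values are adjusted by Benjamini-Hochberg FDR and edges below the FDR
cutoff form the weighted input of the planar network stage.

Per-pair permutation sub-seeds are derived as ``seed XOR crc32(gene_a, gene_b)``
so results do not depend on pair evaluation order; missing values are
handled pairwise complete-case with a minimum of 3 shared observations
(pairs below that are dropped and logged).
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = [
    "permutation_correlation_pvalue",
    "all_pairs_pvalues",
    "fisher_ics",
    "resampling_null_pvalue",
    "bh_fdr",
    "meta_edge_table",
    "significant_edges",
    "EdgeMetaStat",
]

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12
_MIN_OBS = 3


@dataclass(frozen=True)
class EdgeMetaStat:
    """Meta-analysis statistics for one undirected gene pair
    (``gene_a < gene_b`` lexicographically)."""

    gene_a: str
    gene_b: str
    per_cohort_p: tuple
    ics: float
    meta_p: float
    q: float


def _pair_seed(seed: int, gene_a: str, gene_b: str) -> int:
    """Stable per-pair sub-seed, independent of evaluation order."""
    h = zlib.crc32(f"{gene_a}\t{gene_b}".encode())
    return (int(seed) ^ h) & 0x7FFFFFFF


def _standardize(v: np.ndarray) -> np.ndarray:
    c = v - v.mean()
    sd = math.sqrt(float(c @ c))
    return c / sd


def permutation_correlation_pvalue(
    x,
    y,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    method: str = "pearson",
) -> float:
    """Two-sided empirical p-value for the correlation of ``x`` and ``y``.

    Random mode permutes ``y`` ``n_perm`` times and returns the add-one
    estimator ``(1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``, which can
    never be 0. With ``exhaustive=True`` (length <= 8) all permutations of
    ``y`` are enumerated and the exact fraction with ``|r_perm| >= |r_obs|``
    is returned.

    ``method`` is ``"pearson"`` (default) or ``"spearman"`` (ranks first,
    then the same Pearson machinery).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < _MIN_OBS:
        raise ValueError(f"need >= {_MIN_OBS} observations, got {n}")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")

    xs = _standardize(x)
    ys = _standardize(y)
    r_obs = abs(float(xs @ ys))

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to length <= 8")
        hits = total = 0
        for perm in itertools.permutations(ys):
            total += 1
            if abs(float(xs @ np.asarray(perm))) >= r_obs - _TIE_EPS:
                hits += 1
        return hits / total

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    r_perm = np.abs(ys[idx] @ xs)
    exceed = int((r_perm >= r_obs - _TIE_EPS).sum())
    return (1 + exceed) / (n_perm + 1)


def all_pairs_pvalues(
    matrix: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    gene_subset=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Permutation p-values for every unordered gene pair of a cohort.

    Returns a DataFrame with columns ``gene_a``, ``gene_b``, ``p``
    (``gene_a < gene_b``). Pairs with fewer than 3 complete observations
    are omitted and logged. Each pair uses its own seed-derived sub-stream,
    so the table is independent of evaluation order and reproducible.
    """
    if gene_subset is not None:
        genes = sorted(set(gene_subset))
        missing = [g for g in genes if g not in matrix.values.index]
        if missing:
            raise KeyError(f"subset genes absent: {missing[:5]}")
    else:
        genes = sorted(matrix.gene_ids)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes after subsetting")

    values = matrix.values.loc[genes].to_numpy(dtype=float)
    finite = np.isfinite(values)
    rows = []
    n_dropped = 0
    for i, j in itertools.combinations(range(len(genes)), 2):
        mask = finite[i] & finite[j]
        if mask.sum() < _MIN_OBS:
            n_dropped += 1
            logger.info(
                "cohort %s: pair (%s, %s) dropped, only %d complete observations",
                matrix.cohort_id, genes[i], genes[j], int(mask.sum()),
            )
            continue
        a, b = genes[i], genes[j]
        p = permutation_correlation_pvalue(
            values[i, mask],
            values[j, mask],
            n_perm=n_perm,
            seed=_pair_seed(seed, a, b),
            method=method,
        )
        rows.append((a, b, p))
    if n_dropped:
        logger.warning(
            "cohort %s: dropped %d pair(s) with < %d complete observations",
            matrix.cohort_id, n_dropped, _MIN_OBS,
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "p"])


def fisher_ics(pvals) -> float:
    """Fisher's inverse chi-square statistic, ``-2 * sum(ln p)``."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


def resampling_null_pvalue(
    ics_obs: float,
    pvalue_pool,
    k: int,
    n_resample: int = 10000,
    seed: int = 0,
) -> float:
    """Empirical meta p-value for an observed ICS against a resampling null.

    Draws ``k`` p-values with replacement from ``pvalue_pool`` ``n_resample``
    times, forms the ICS of each draw, and returns the add-one tail fraction
    ``(1 + #{ICS_null >= ics_obs}) / (n_resample + 1)``. Ties count as >=.
    """
    pool = np.asarray(list(pvalue_pool), dtype=float)
    if pool.size == 0:
        raise ValueError("empty p-value pool")
    if k < 1:
        raise ValueError("k must be >= 1")
    null = sample_null_ics(pool, k, n_resample, seed)
    exceed = int((null >= ics_obs - _TIE_EPS).sum())
    return (1 + exceed) / (n_resample + 1)


def sample_null_ics(pool: np.ndarray, k: int, n_resample: int, seed: int) -> np.ndarray:
    """Draw ``n_resample`` null ICS values by resampling ``k`` p-values with
    replacement from ``pool`` (the shared null distribution of the meta
    stage)."""
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(n_resample, k), replace=True)
    return -2.0 * np.log(draws).sum(axis=1)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_edge_table(
    cohorts,
    n_perm: int = 1000,
    seed: int = 0,
    gene_subset=None,
    top_var: int = 500,
    n_resample: int = 10000,
    method: str = "pearson",
) -> pd.DataFrame:
    """Full cross-cohort edge meta-analysis.

    Computes per-cohort permutation p-values for every gene pair (on the
    caller's subset, or the ``top_var`` highest-variance shared genes),
    combines them with Fisher's ICS, evaluates each ICS against a single
    resampling null built from the pool of all observed nominal p-values
    (10,000 draws by default), and BH-adjusts the meta p-values.

    Returns a DataFrame with columns ``gene_a``, ``gene_b``,
    ``p_cohort_1..k``, ``ics``, ``meta_p``, ``q``.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("no cohorts supplied")
    shared = set(cohorts[0].gene_ids)
    for m in cohorts[1:]:
        shared &= set(m.gene_ids)
    if gene_subset is not None:
        genes = sorted(set(gene_subset) & shared)
    else:
        genes = sorted(shared)
        if top_var is not None and len(genes) > top_var:
            pooled_var = sum(
                m.values.loc[genes].var(axis=1, ddof=1) for m in cohorts
            )
            genes = sorted(pooled_var.nlargest(top_var).index)
    if len(genes) < 2:
        raise ValueError("fewer than 2 shared genes after subsetting")

    per_cohort = []
    for ci, mat in enumerate(cohorts):
        tab = all_pairs_pvalues(
            mat, n_perm=n_perm, seed=_pair_seed(seed, "cohort", str(ci)),
            gene_subset=genes, method=method,
        )
        per_cohort.append(tab.set_index(["gene_a", "gene_b"])["p"])

    merged = pd.concat(per_cohort, axis=1, join="inner")
    merged.columns = [f"p_cohort_{i + 1}" for i in range(len(cohorts))]
    if merged.empty:
        raise ValueError("no gene pair observed in every cohort")

    pmat = merged.to_numpy()
    ics = -2.0 * np.log(pmat).sum(axis=1)

    pool = pmat.ravel()
    null = np.sort(sample_null_ics(pool, len(cohorts), n_resample,
                                   _pair_seed(seed, "resampling", "null")))
    # shared null: per-edge p via the add-one tail of the same null sample
    exceed = null.size - np.searchsorted(null, ics - _TIE_EPS, side="left")
    meta_p = (1 + exceed) / (n_resample + 1)

    out = merged.reset_index()
    out["ics"] = ics
    out["meta_p"] = meta_p
    out["q"] = bh_fdr(meta_p)
    return out


def significant_edges(edge_stats: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Edges passing the FDR cutoff, weighted by ICS.

    Returns columns ``gene_a``, ``gene_b``, ``weight`` sorted by weight
    descending with a lexicographic tie-break on (gene_a, gene_b). An empty
    result is allowed.
    """
    if "q" not in edge_stats.columns:
        raise ValueError("edge table lacks a 'q' column; run meta_edge_table first")
    kept = edge_stats.loc[edge_stats["q"] < q_threshold,
                          ["gene_a", "gene_b", "ics"]].copy()
    kept = kept.rename(columns={"ics": "weight"})
    kept = kept.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return kept
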