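"""Key driver analysis: rank module genes by n-layer neighborhood enrichment.

A candidate driver's "downstream" genes are its n-hop breadth-first
neighborhood in the planar coexpression network. For each module gene the
hypergeometric enrichment of module members within that neighborhood is
evaluated at n = 1..n_max and the depth maximizing -log10 p is kept
(tie-break: smaller n). Selected p-values are BH-adjusted across the
module's genes and results ranked by (q, fold enrichment, gene id).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .coexpr import bh_fdr
from .enrichment import hypergeometric_tail
from .network import GeneModule, PlanarNetwork

__all__ = [
    "KeyDriverResult",
    "n_layer_neighborhood",
    "neighborhood_enrichment",
    "key_driver_analysis",
]


@dataclass(frozen=True)
class KeyDriverResult:
    gene: str
    module_id: str
    optimal_n: int
    neighborhood_size: int
    overlap: int
    fold_enrichment: float
    p: float
    q: float
    rank: int


def n_layer_neighborhood(network: PlanarNetwork, gene: str, n: int) -> set:
    """Nodes at hop distance 1..n from ``gene`` (gene itself excluded);
    n = 0 returns the empty set."""
    if gene not in network.graph:
        raise KeyError(f"gene {gene!r} not in network")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return set()
    dist = nx.single_source_shortest_path_length(network.graph, gene, cutoff=n)
    return {v for v, d in dist.items() if d >= 1}


def neighborhood_enrichment(neighborhood, module, universe) -> tuple[float, float]:
    """Fold enrichment and hypergeometric upper-tail p of module members in
    a neighborhood.

    fold = (|overlap| / |neighborhood|) / (|module| / |universe|);
    p = P(X >= |overlap|) for X hypergeometric with population |universe|,
    |module| successes and |neighborhood| draws.
    """
    neighborhood = set(neighborhood)
    module = set(module)
    universe = set(universe)
    if not neighborhood:
        raise ValueError("empty neighborhood")
    if not module:
        raise ValueError("empty module")
    if not neighborhood <= universe or not module <= universe:
        raise ValueError("neighborhood and module must be subsets of the universe")
    overlap = len(neighborhood & module)
    fold = (overlap / len(neighborhood)) / (len(module) / len(universe))
    p = hypergeometric_tail(overlap, len(module), len(neighborhood), len(universe))
    return fold, p


def key_driver_analysis(
    network: PlanarNetwork,
    module: GeneModule,
    universe=None,
    n_max: int = 5,
    candidates=None,
) -> list[KeyDriverResult]:
    """Rank a module's genes as candidate key drivers.

    For every candidate gene (all module members by default) the
    neighborhood enrichment is evaluated at n = 1..n_max; the depth with
    the smallest p wins (ties to the smaller n). BH adjustment is applied
    across the module's candidates; output is sorted by (q ascending, fold
    descending, gene id) and ranked 1..K.

    ``universe`` defaults to all network nodes; ``candidates`` may restrict
    the search (e.g. to hub nodes).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    universe = set(universe) if universe is not None else set(network.graph.nodes)
    members = set(module.members)
    missing = members - set(network.graph.nodes)
    if missing:
        raise KeyError(f"module genes absent from network: {sorted(missing)[:5]}")
    genes = sorted(set(candidates) & members) if candidates is not None else sorted(members)
    if not genes:
        raise ValueError("no candidate genes in module")

    picked = []
    for gene in genes:
        best = None  # (p, n, fold, nb_size, overlap)
        for n in range(1, n_max + 1):
            nb = n_layer_neighborhood(network, gene, n)
            if not nb:
                continue
            fold, p = neighborhood_enrichment(nb, members, universe)
            if best is None or p < best[0]:
                best = (p, n, fold, len(nb), len(nb & members))
        if best is None:  # isolated gene: vacuous result
            best = (1.0, 1, 0.0, 0, 0)
        picked.append((gene, *best))

    qs = bh_fdr([rec[1] for rec in picked])
    rows = sorted(
        (
            (q, -fold, gene, p, n, nb_size, overlap)
            for (gene, p, n, fold, nb_size, overlap), q in zip(picked, qs)
        )
    )
    results = []
    for rank, (q, neg_fold, gene, p, n, nb_size, overlap) in enumerate(rows, 1):
        results.append(
            KeyDriverResult(
                gene=gene,
                module_id=module.module_id,
                optimal_n=n,
                neighborhood_size=nb_size,
                overlap=overlap,
                fold_enrichment=-neg_fold,
                p=p,
                q=float(q),
                rank=rank,
            )
        )
    return results


def key_driver_table(results) -> pd.DataFrame:
    """Flatten KeyDriverResult lists (one or more modules) to a DataFrame."""
    flat = [r for sub in results for r in (sub if isinstance(sub, list) else [sub])]
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "module_id": r.module_id,
                "optimal_n": r.optimal_n,
                "neighborhood_size": r.neighborhood_size,
                "overlap": r.overlap,
                "fold_enrichment": r.fold_enrichment,
                "p": r.p,
                "q": r.q,
                "rank": r.rank,
            }
            for r in flat
        ]
    )
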