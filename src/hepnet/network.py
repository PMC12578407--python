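"""Planar maximally filtered graph construction and multiscale module
detection.

The significant-edge list from the meta-analysis stage is filtered to a
planar backbone with the classical PMFG greedy rule: visit edges by weight
descending (lexicographic tie-break), insert an edge iff the graph stays
planar, stop once 3(|V|-2) edges are accepted. Gene modules are then
extracted by greedy modularity optimization at a sweep of resolution
parameters, and each module is annotated with the scale-free topology fit
index (R^2 of log10 P(k) vs log10 k) of its induced subgraph — reported as
a diagnostic, not enforced as a hard filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "PlanarNetwork",
    "GeneModule",
    "build_pmfg",
    "detect_modules_multiscale",
    "scale_free_fit",
]

DEFAULT_SCALES = (0.5, 1.0, 2.0)


@dataclass
class PlanarNetwork:
    """A planar weighted gene graph plus the construction audit trail.

    ``construction_log`` holds one ``(gene_a, gene_b, weight, decision)``
    tuple per input edge, decision in {"accepted", "rejected"}.
    """

    graph: nx.Graph
    construction_log: list = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]

    def to_json_dict(self) -> dict:
        return {
            "nodes": sorted(self.graph.nodes),
            "edges": sorted(
                [a, b, d["weight"]] if a < b else [b, a, d["weight"]]
                for a, b, d in self.graph.edges(data=True)
            ),
            "construction_log": [list(rec) for rec in self.construction_log],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PlanarNetwork":
        g = nx.Graph()
        g.add_nodes_from(d["nodes"])
        for a, b, w in d["edges"]:
            g.add_edge(a, b, weight=float(w))
        return cls(g, [tuple(rec) for rec in d.get("construction_log", [])])


@dataclass
class GeneModule:
    """One detected gene module at one resolution scale."""

    module_id: str
    members: frozenset
    scale: float
    scale_free_r2: float  # NaN when the degree fit is undefined

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))


def build_pmfg(edges, nodes) -> PlanarNetwork:
    """Greedy planar maximally filtered graph.

    ``edges`` is an iterable of ``(gene_a, gene_b, weight)``; ``nodes`` must
    cover all edge endpoints (isolated nodes are kept in the graph). Edges
    are visited by weight descending, ties broken lexicographically on the
    canonical (min, max) pair; an edge is inserted iff the graph remains
    planar; construction stops when 3(|V|-2) edges are accepted or the list
    is exhausted. Self-loops and duplicate edges are errors.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty node list")
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate node ids")
    node_set = set(nodes)

    canon = []
    seen = set()
    for a, b, w in edges:
        if a == b:
            raise ValueError(f"self-loop on {a}")
        if a not in node_set or b not in node_set:
            raise ValueError(f"edge endpoint not in node list: ({a}, {b})")
        if not math.isfinite(float(w)):
            raise ValueError(f"non-finite weight on ({a}, {b})")
        key = (a, b) if a < b else (b, a)
        if key in seen:
            raise ValueError(f"duplicate edge ({key[0]}, {key[1]})")
        seen.add(key)
        canon.append((key[0], key[1], float(w)))

    canon.sort(key=lambda e: (-e[2], e[0], e[1]))

    n = len(nodes)
    max_edges = 3 * (n - 2) if n >= 3 else n * (n - 1) // 2
    g = nx.Graph()
    g.add_nodes_from(nodes)
    log: list[tuple[str, str, float, str]] = []
    accepted = 0
    for a, b, w in canon:
        if accepted >= max_edges:
            log.append((a, b, w, "rejected"))
            continue
        g.add_edge(a, b, weight=w)
        planar, _ = nx.check_planarity(g)
        if planar:
            accepted += 1
            log.append((a, b, w, "accepted"))
        else:
            g.remove_edge(a, b)
            log.append((a, b, w, "rejected"))

    assert nx.check_planarity(g)[0]
    return PlanarNetwork(g, log)


def scale_free_fit(degrees) -> float:
    """Scale-free topology fit index of a degree sequence.

    R^2 of the least-squares line through (log10 k, log10 P(k)). Distinct
    positive degree values serve directly as log-bins when there are at
    most 12 of them (an exact power law then fits with R^2 = 1); larger
    supports are geometrically binned into at most 10 occupied bins.
    Raises if fewer than 2 distinct positive degrees exist.
    """
    k = np.asarray(list(degrees), dtype=float)
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("no positive degrees")
    uniq, counts = np.unique(k, return_counts=True)
    if uniq.size < 2:
        raise ValueError("all degrees equal: scale-free fit undefined")

    if uniq.size <= 12:
        log_k = np.log10(uniq)
        log_p = np.log10(counts / k.size)
    else:
        edges = np.geomspace(uniq.min(), uniq.max() * (1 + 1e-9), 11)
        which = np.clip(np.digitize(k, edges) - 1, 0, 9)
        log_k_list, log_p_list = [], []
        for b in range(10):
            in_bin = k[which == b]
            if in_bin.size == 0:
                continue
            log_k_list.append(np.log10(stats.gmean(in_bin)))
            log_p_list.append(np.log10(in_bin.size / k.size))
        log_k = np.asarray(log_k_list)
        log_p = np.asarray(log_p_list)
        if log_k.size < 2:
            raise ValueError("degree distribution collapses to one log-bin")

    fit = stats.linregress(log_k, log_p)
    return float(fit.rvalue ** 2)


def _module_sort_key(members) -> tuple:
    return (-len(members), min(members))


def detect_modules_multiscale(
    network: PlanarNetwork,
    scales=DEFAULT_SCALES,
    min_size: int = 10,
) -> list[GeneModule]:
    """Greedy-modularity communities of the planar graph at each resolution.

    Communities with at least ``min_size`` members are kept; each is
    annotated with its detection scale and the scale-free fit of its
    induced-subgraph degree sequence (NaN when undefined). Module ids are
    deterministic: communities are ordered by size descending then by
    smallest member id, within each scale.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    scales = list(scales)
    if not scales:
        raise ValueError("no scales supplied")
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")

    modules: list[GeneModule] = []
    for scale in scales:
        communities = nx.community.greedy_modularity_communities(
            g, weight="weight", resolution=scale
        )
        kept = sorted(
            (frozenset(c) for c in communities if len(c) >= min_size),
            key=_module_sort_key,
        )
        for idx, members in enumerate(kept, 1):
            sub_degrees = [d for _, d in g.subgraph(members).degree()]
            try:
                r2 = scale_free_fit(sub_degrees)
            except ValueError:
                r2 = float("nan")
            modules.append(
                GeneModule(f"S{scale:g}_M{idx}", members, float(scale), r2)
            )
    return modules
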