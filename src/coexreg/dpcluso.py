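"""Overlapping density-based graph clustering (DPClusO-style).

Clusters are grown greedily from high-degree seeds. Growth is
constrained by two quantities: the cluster *density*
``d_k = E_k / (N_k (N_k - 1) / 2)`` must stay at or above ``d_min``
after every addition, and the joining node's *cluster property*
``cp_nk = E_nk / (d_k * N_k)`` — its edge count into the cluster
relative to what the cluster's density would predict — must be at least
``cp_min``. Emitted members stay in the graph, so later clusters may
overlap earlier ones.

All tie-breaks are by node identifier, making the output a pure
function of the graph and the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx


@dataclass(frozen=True)
class DPClusOParams:
    d_min: float = 0.5
    cp_min: float = 0.5
    min_cluster_size: int = 2

    DENSITY_SWEEP = (0.5, 0.6, 0.7, 0.8, 0.9)

    def __post_init__(self):
        if not 0.0 < self.d_min <= 1.0:
            raise ValueError("d_min must lie in (0, 1]")
        if self.cp_min < 0:
            raise ValueError("cp_min must be non-negative")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    nodes: Tuple[str, ...]
    n_edges: int
    # members in the order the growth added them (seed first); empty for
    # clusters constructed from a plain node list
    growth_order: Tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def density(self) -> float:
        n = self.size
        if n < 2:
            return 1.0
        return self.n_edges / (n * (n - 1) / 2)


@dataclass
class ClusterSet:
    clusters: List[Cluster]
    d_min: float
    params: DPClusOParams = field(default_factory=DPClusOParams)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def membership(self) -> Dict[str, List[str]]:
        """node → ids of clusters containing it (overlap allowed)."""
        out: Dict[str, List[str]] = {}
        for cluster in self.clusters:
            for node in cluster.nodes:
                out.setdefault(node, []).append(cluster.cluster_id)
        return out


def cluster_density(nodes: Iterable[str], graph: nx.Graph) -> float:
    """Internal edge count over the maximum possible; singleton → 1."""
    members = list(nodes)
    n = len(members)
    if n < 1:
        raise ValueError("empty node set has no density")
    if n == 1:
        return 1.0
    e = graph.subgraph(members).number_of_edges()
    return e / (n * (n - 1) / 2)


def cluster_property(
    node: str, cluster_nodes: Iterable[str], graph: nx.Graph, d_k: float
) -> float:
    """cp_nk = E_nk / (d_k * N_k): node n's pull toward cluster k."""
    members = set(cluster_nodes)
    if node in members:
        raise ValueError(f"{node!r} is already a member of the cluster")
    if d_k <= 0:
        raise ValueError("cluster property undefined at zero density")
    e_nk = sum(1 for m in members if graph.has_edge(node, m))
    return e_nk / (d_k * len(members))


def _grow_cluster(
    graph: nx.Graph, seed: str, params: DPClusOParams
) -> Tuple[List[str], int, List[str]]:
    """Grow one cluster from a seed under the density and cp constraints."""
    members: Set[str] = {seed}
    order: List[str] = [seed]
    n_edges = 0
    while True:
        n_k = len(members)
        d_k = 1.0 if n_k == 1 else n_edges / (n_k * (n_k - 1) / 2)
        candidates: List[Tuple[int, str]] = []
        neighbourhood = set()
        for m in members:
            neighbourhood.update(graph.neighbors(m))
        for cand in neighbourhood - members:
            e_nk = sum(1 for m in members if graph.has_edge(cand, m))
            new_density = (n_edges + e_nk) / ((n_k + 1) * n_k / 2)
            if new_density < params.d_min:
                continue
            if d_k > 0:
                cp = e_nk / (d_k * n_k)
                if cp < params.cp_min:
                    continue
            candidates.append((e_nk, cand))
        if not candidates:
            break
        # most edges into the cluster wins; ties to the smallest node id
        candidates.sort(key=lambda pair: (-pair[0], pair[1]))
        e_nk, chosen = candidates[0]
        members.add(chosen)
        order.append(chosen)
        n_edges += e_nk
    return sorted(members), n_edges, order


def dpcluso_cluster(graph: nx.Graph, params: DPClusOParams = DPClusOParams()) -> ClusterSet:
    """Greedy seeded growth of overlapping dense clusters.

    Seeds are uncovered nodes in decreasing degree order (ties by node
    id). Emitted clusters mark their members covered but members remain
    available to later clusters, so overlaps arise naturally. Every
    emitted cluster is connected, has density >= ``d_min`` and size >=
    ``min_cluster_size``.
    """
    order = sorted(graph.nodes, key=lambda n: (-graph.degree(n), str(n)))
    covered: Set[str] = set()
    clusters: List[Cluster] = []
    for seed in order:
        if seed in covered:
            continue
        members, n_edges, order = _grow_cluster(graph, seed, params)
        covered.update(members)
        if len(members) >= params.min_cluster_size:
            clusters.append(
                Cluster(f"C{len(clusters) + 1}", tuple(members), n_edges, tuple(order))
            )
    return ClusterSet(clusters, params.d_min, params)


def density_sweep(
    graph: nx.Graph,
    densities: Sequence[float] = DPClusOParams.DENSITY_SWEEP,
    cp_min: float = 0.5,
    min_cluster_size: int = 2,
) -> Dict[float, ClusterSet]:
    """Run the clustering once per density threshold."""
    return {
        d: dpcluso_cluster(
            graph, DPClusOParams(d_min=d, cp_min=cp_min, min_cluster_size=min_cluster_size)
        )
        for d in densities
    }
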