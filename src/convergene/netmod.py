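"""Evidence-filtered protein interaction network, MCL clustering, hubs.

The network is built around a set of seed proteins (the prioritized genes)
and their direct interactors.  To limit false-positive interactions, only
edges supported by at least two experimental validations are admitted; a
seed left without any such partner falls back to its single-validation
edges.  The union is cleaned of self loops, duplicate pairs and isolated
nodes, and each node is assigned one of eight subcellular-compartment
layers (or "unknown").

Clustering uses the Markov Cluster algorithm (MCL), implemented here from
first principles: the column-stochastic adjacency (with unit self loops) is
alternately expanded (matrix squaring — flow spreads) and inflated
(entrywise powering with column renormalization — strong flow is favoured)
until a fixed point; clusters are read off the limit matrix's attractor
structure.  Each reported cluster carries a hub: its highest-degree member.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .iotables import COMPARTMENTS

__all__ = [
    "InteractionNetwork",
    "MCLParams",
    "ClusterSet",
    "build_network",
    "assign_layers",
    "mcl_cluster",
    "find_hubs",
    "DEFAULT_COMPARTMENT_PRIORITY",
]

#: Resolution order when a protein is annotated to several compartments.
DEFAULT_COMPARTMENT_PRIORITY = COMPARTMENTS


@dataclasses.dataclass
class InteractionNetwork:
    """Undirected evidence-weighted protein graph.

    Edge attributes: ``evidence_count`` (int >= 1) and ``provenance``
    (``two_plus`` | ``one_fallback``).  Node attribute ``layer`` holds the
    compartment after :func:`assign_layers`.
    """

    graph: nx.Graph

    def __post_init__(self):
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self loops are not allowed")

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self):
        import pandas as pd

        rows = [
            {
                "protein_a": min(u, v),
                "protein_b": max(u, v),
                "evidence_count": d.get("evidence_count", 1),
                "provenance": d.get("provenance", ""),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        rows.sort(key=lambda r: (r["protein_a"], r["protein_b"]))
        return pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "evidence_count", "provenance"]
        )

    def layer_counts(self) -> dict:
        counts: dict[str, int] = {}
        for _, layer in self.graph.nodes(data="layer", default="unknown"):
            counts[layer] = counts.get(layer, 0) + 1
        return dict(sorted(counts.items()))


def build_network(seed_proteins, edges) -> InteractionNetwork:
    """Assemble the evidence-filtered seed-plus-interactors network.

    Network A keeps seed-incident edges with ``evidence_count >= 2``; any
    seed with no edge in A contributes its single-validation edges as
    network B.  The result is the deduplicated union with self loops and
    isolated nodes removed, and each edge tagged with the rule that admitted
    it.  Output is invariant to edge-row order.
    """
    seeds = {s for s in seed_proteins}
    if not seeds:
        raise ValueError("empty seed protein set")

    # canonical unordered pairs, drop self loops, keep max evidence per pair
    pair_ev: dict[tuple, int] = {}
    for _, row in edges.iterrows():
        a, b = row["protein_a"], row["protein_b"]
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        ev = int(row["evidence_count"])
        if key not in pair_ev or ev > pair_ev[key]:
            pair_ev[key] = ev

    seed_incident = {k: v for k, v in pair_ev.items() if k[0] in seeds or k[1] in seeds}
    net_a = {k: v for k, v in seed_incident.items() if v >= 2}
    covered = {p for pair in net_a for p in pair if p in seeds}
    lonely = seeds - covered
    net_b = {
        k: v
        for k, v in seed_incident.items()
        if k not in net_a and (k[0] in lonely or k[1] in lonely)
    }

    graph = nx.Graph()
    for (a, b), ev in sorted(net_a.items()):
        graph.add_edge(a, b, evidence_count=ev, provenance="two_plus")
    for (a, b), ev in sorted(net_b.items()):
        graph.add_edge(a, b, evidence_count=ev, provenance="one_fallback")
    graph.remove_nodes_from(list(nx.isolates(graph)))
    return InteractionNetwork(graph=graph)


def assign_layers(
    network: InteractionNetwork,
    localization: dict | None,
    priority=DEFAULT_COMPARTMENT_PRIORITY,
) -> InteractionNetwork:
    """Label every node with one compartment layer, or "unknown".

    ``localization`` maps protein -> compartment or protein -> iterable of
    compartments; multi-compartment proteins resolve to the first compartment
    in ``priority``.  Unannotated proteins become "unknown".
    """
    localization = localization or {}
    rank = {c: i for i, c in enumerate(priority)}
    for node in network.graph.nodes:
        ann = localization.get(node)
        if ann is None:
            layer = "unknown"
        elif isinstance(ann, str):
            layer = ann if ann in rank else "unknown"
        else:
            known = sorted((c for c in ann if c in rank), key=rank.__getitem__)
            layer = known[0] if known else "unknown"
        network.graph.nodes[node]["layer"] = layer
    return network


@dataclasses.dataclass(frozen=True)
class MCLParams:
    inflation: float = 2.0
    pruning_threshold: float = 1e-5
    convergence_tolerance: float = 1e-8
    max_iterations: int = 200

    def __post_init__(self):
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")
        if self.pruning_threshold < 0:
            raise ValueError("pruning_threshold must be >= 0")


@dataclasses.dataclass
class ClusterSet:
    """An MCL partition with one hub per reported cluster.

    ``clusters`` are disjoint sorted node lists, ordered by descending size
    then lexicographically by first member.  ``hubs`` maps cluster index to
    its hub node; ``significant`` lists the indices of clusters at or above
    the reportable minimum size.
    """

    clusters: list
    hubs: dict
    params: MCLParams | None = None
    min_significant_size: int = 5

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def significant(self) -> list:
        return [
            i for i, c in enumerate(self.clusters) if len(c) >= self.min_significant_size
        ]

    def membership(self) -> dict:
        return {node: i for i, cluster in enumerate(self.clusters) for node in cluster}

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "cluster_id": i,
                "size": len(cluster),
                "hub": self.hubs.get(i, ""),
                "significant": len(cluster) >= self.min_significant_size,
                "members": ",".join(cluster),
            }
            for i, cluster in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows, columns=["cluster_id", "size", "hub", "significant", "members"]
        )


def _column_normalize(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_cluster(network: InteractionNetwork, params: MCLParams = MCLParams()) -> ClusterSet:
    """Partition the network with the Markov Cluster algorithm.

    Unit self loops are added, columns normalized, then expansion (matrix
    squaring) alternates with inflation (entrywise power ``inflation``,
    column renormalization) and pruning of entries below
    ``pruning_threshold``, until the max absolute entry change falls below
    ``convergence_tolerance``.  Clusters are the attractor systems of the
    limit matrix: rows with positive diagonal mass are attractors,
    overlapping attractor rows merge, and every node joins the cluster of
    the (lexicographically smallest) attractor that supports it.
    """
    nodes = network.nodes
    if not nodes:
        raise ValueError("cannot cluster an empty network")
    n = len(nodes)
    adj = nx.to_numpy_array(network.graph, nodelist=nodes, weight=None)
    np.fill_diagonal(adj, 1.0)  # self loops stabilise odd-length cycles
    m = _column_normalize(adj)

    for _ in range(params.max_iterations):
        expanded = m @ m
        inflated = np.power(expanded, params.inflation)
        inflated[inflated < params.pruning_threshold] = 0.0
        inflated = _column_normalize(inflated)
        residual = np.abs(inflated - m).max()
        m = inflated
        if residual < params.convergence_tolerance:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {params.max_iterations} iterations "
            f"(last residual {residual:.3e})"
        )

    support_eps = max(params.pruning_threshold, 1e-12)
    attractors = [i for i in range(n) if m[i, i] > support_eps]
    if not attractors:  # degenerate fallback: every node its own attractor
        attractors = list(range(n))
    support = {i: set(np.nonzero(m[i] > support_eps)[0]) | {i} for i in attractors}

    # merge attractor rows that share any supported node (attractor systems)
    parent = {i: i for i in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    owner: dict[int, int] = {}
    for i in attractors:
        for j in support[i]:
            if j in owner:
                a, b = find(owner[j]), find(i)
                if a != b:
                    parent[max(a, b)] = min(a, b)
            else:
                owner[j] = i

    systems: dict[int, set] = {}
    for i in attractors:
        systems.setdefault(find(i), set()).update(support[i])

    assignment: dict[int, int] = {}
    for root in sorted(systems):
        for j in sorted(systems[root]):
            if j not in assignment:  # tie -> smallest attractor root wins
                assignment[j] = root
    for j in range(n):  # unsupported nodes (fully pruned) become singletons
        assignment.setdefault(j, j)

    groups: dict[int, list] = {}
    for j, root in assignment.items():
        groups.setdefault(root, []).append(nodes[j])
    clusters = sorted(
        (sorted(g) for g in groups.values()), key=lambda c: (-len(c), c[0])
    )
    out = ClusterSet(clusters=clusters, hubs={}, params=params)
    out.hubs = find_hubs(out, network)
    return out


def find_hubs(clusters: ClusterSet, network: InteractionNetwork) -> dict:
    """Hub per cluster: maximum degree within the cluster-induced subgraph.

    Ties break by whole-network degree, then lexicographically.  Returned for
    every cluster; the ``significant`` property of the ClusterSet restricts
    reporting to clusters at or above the minimum size.
    """
    hubs = {}
    for i, members in enumerate(clusters.clusters):
        sub = network.graph.subgraph(members)
        hubs[i] = min(
            members,
            key=lambda node: (-sub.degree(node), -network.graph.degree(node), node),
        )
    return hubs
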