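"""Random walk with restart (RWR) over an interaction network.

Network-propagation scoring of candidate genes by proximity to seed genes:
the walker steps along edges of the (unweighted, column-normalized) network
and at each step restarts at a seed with probability ``r``.  The stationary
distribution

    p = (1 - r) W p + r p0

scores every node; candidate genes are ranked by their stationary
probability.  This is the prioritization strategy used for ranking genes in
linkage intervals.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

__all__ = ["RWRParams", "rwr_scores", "prioritize_candidates"]


@dataclasses.dataclass(frozen=True)
class RWRParams:
    """Restart probability, L1 convergence tolerance and iteration cap."""

    restart_probability: float = 0.75
    tolerance: float = 1e-6
    max_iterations: int = 10_000

    def __post_init__(self):
        if not (0.0 < self.restart_probability <= 1.0):
            raise ValueError("restart_probability must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph  # InteractionNetwork


def rwr_scores(network, seeds, params: RWRParams = RWRParams()) -> dict:
    """Steady-state visiting probabilities from a uniform restart over seeds.

    Iterates ``p <- (1-r) W p + r p0`` with W the column-normalized adjacency
    and p0 uniform over the seeds present in the network, until the L1 change
    drops below ``tolerance``.  The returned probabilities sum to 1 (within
    tolerance).  Deterministic: node order is sorted.
    """
    graph = _as_graph(network)
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    present = sorted(set(seeds) & set(nodes))
    if not present:
        raise ValueError("no seed gene is present in the network")

    n = len(nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    colsum = adj.sum(axis=0)
    w = np.divide(adj, colsum, out=np.zeros_like(adj), where=colsum > 0)
    # dangling nodes (degree 0 after cleanup shouldn't exist, but restart
    # absorbs any lost mass only when r=1; reinject to seeds to conserve)
    dangling = colsum == 0

    p0 = np.zeros(n)
    p0[[index[s] for s in present]] = 1.0 / len(present)
    r = params.restart_probability
    p = p0.copy()
    for _ in range(params.max_iterations):
        spread = w @ p
        lost = p[dangling].sum()
        nxt = (1.0 - r) * (spread + lost * p0) + r * p0
        residual = np.abs(nxt - p).sum()
        p = nxt
        if residual < params.tolerance:
            return {node: float(p[index[node]]) for node in nodes}
    raise RuntimeError(
        f"RWR did not converge in {params.max_iterations} iterations "
        f"(last L1 residual {residual:.3e})"
    )


def prioritize_candidates(candidates, scores: dict):
    """Rank candidate genes descending by RWR score.

    Candidates absent from the network score 0 and sort after all scored
    candidates; ties break lexicographically.  Returns a DataFrame with
    columns symbol, score, rank.
    """
    import pandas as pd

    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    rows = sorted(
        ((c, float(scores.get(c, 0.0))) for c in candidates),
        key=lambda cs: (-cs[1], cs[0]),
    )
    return pd.DataFrame(
        {
            "symbol": [c for c, _ in rows],
            "score": [s for _, s in rows],
            "rank": range(1, len(rows) + 1),
        }
    )
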