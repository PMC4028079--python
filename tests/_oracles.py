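"""Independent reference implementations used as test oracles.

Deliberately naive and written without reference to the package internals:
plain-Python loops, direct definitions, closed forms.  They verify the
package's optimised implementations on small inputs.
"""

from __future__ import annotations

import math


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct mass summation."""

    def comb(a, b):
        return math.comb(a, b) if 0 <= b <= a else 0

    denom = comb(N, n)
    total = sum(comb(K, x) * comb(N - K, n - x) for x in range(max(k, 0), min(n, K) + 1))
    return total / denom


def bh_stepup(pvals: list) -> list:
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        value = min(1.0, pvals[i] * m / (pos + 1))
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def rwr_linear_solve(graph, seeds, r: float) -> dict:
    """Closed-form stationary RWR: p = r (I - (1-r) W)^-1 p0 via numpy solve."""
    import numpy as np

    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u in nodes:
        nbrs = list(graph.neighbors(u))
        for v in nbrs:
            w[idx[v], idx[u]] = 1.0 / len(nbrs)
    p0 = np.zeros(n)
    present = [s for s in seeds if s in idx]
    for s in present:
        p0[idx[s]] = 1.0 / len(present)
    p = r * np.linalg.solve(np.eye(n) - (1.0 - r) * w, p0)
    return {v: float(p[idx[v]]) for v in nodes}


def reference_mcl(graph, inflation: float, max_iter: int = 200,
                  tol: float = 1e-8, prune: float = 1e-5):
    """Plain-Python MCL on a dict-of-dicts matrix; returns frozenset partition.

    Same algorithm definition as any MCL: unit self loops, column-stochastic
    start, square/inflate/prune until stable, clusters from attractor rows.
    Implementation shares no code with the package (nested dicts, loops).
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    # column-major: matrix[j] is the column of node j
    matrix = [[0.0] * n for _ in range(n)]
    for u, v in graph.edges:
        matrix[index[u]][index[v]] = 1.0
        matrix[index[v]][index[u]] = 1.0
    for j in range(n):
        matrix[j][j] = 1.0
    for j in range(n):
        s = sum(matrix[j])
        matrix[j] = [x / s for x in matrix[j]]

    for _ in range(max_iter):
        # expansion: new[j][i] = sum_k old[k][i] * old[j][k]
        new = [[0.0] * n for _ in range(n)]
        for j in range(n):
            col = matrix[j]
            for k in range(n):
                w = col[k]
                if w == 0.0:
                    continue
                colk = matrix[k]
                for i in range(n):
                    new[j][i] += colk[i] * w
        # inflation + prune + renormalize
        for j in range(n):
            col = [x**inflation for x in new[j]]
            col = [0.0 if x < prune else x for x in col]
            s = sum(col) or 1.0
            new[j] = [x / s for x in col]
        diff = max(
            abs(new[j][i] - matrix[j][i]) for j in range(n) for i in range(n)
        )
        matrix = new
        if diff < tol:
            break

    eps = max(prune, 1e-12)
    attractors = [i for i in range(n) if matrix[i][i] > eps]
    clusters = []
    assigned = set()
    for i in sorted(attractors):
        members = {j for j in range(n) if matrix[j][i] > eps} | {i}
        hit = [c for c in clusters if c & members]
        merged = set(members)
        for c in hit:
            merged |= c
            clusters.remove(c)
        clusters.append(merged)
    for cluster in clusters:
        assigned |= cluster
    for j in range(n):
        if j not in assigned:
            clusters.append({j})
    # overlapping nodes: keep in the cluster of the smallest attractor; with
    # merged attractor systems overlap is already resolved by the union step
    return {frozenset(nodes[j] for j in c) for c in clusters}
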