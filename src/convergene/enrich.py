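"""Term enrichment with EASE/Fisher statistics and kappa annotation clustering.

Per-term over-representation of a query gene set against an annotation
universe is tested with the one-sided hypergeometric upper tail (Fisher) or
its conservative jackknifed variant (EASE: one hit gene removed before the
tail is taken), followed by Benjamini–Hochberg adjustment.  Terms are then
grouped into functional annotation clusters: terms whose gene memberships
agree beyond chance (Cohen's kappa over the universe) seed groups that are
merged while they share enough members, and each cluster's enrichment score
is -log10 of the geometric mean of its members' raw p-values; a score of
1.3 (mean p ~ 0.05) is the significance boundary.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TermRecord",
    "AnnotationCluster",
    "EnrichmentReport",
    "term_pvalue",
    "bh_adjust",
    "kappa_similarity",
    "cluster_terms",
    "enrichment_score",
    "enrich_query",
]

SIGNIFICANT_ENRICHMENT_SCORE = 1.3


@dataclasses.dataclass(frozen=True)
class TermRecord:
    term_id: str
    term_name: str
    namespace: str  # BP | MF | CC
    annotated_genes: frozenset

    def __post_init__(self):
        if self.namespace not in ("BP", "MF", "CC"):
            raise ValueError(f"namespace must be BP|MF|CC, got {self.namespace!r}")


def term_pvalue(k, n: int, K: int, N: int, method: str = "ease"):
    """Over-representation p-value for k query hits in a term.

    Parameters are the 2x2 margins: ``k`` hits among ``n`` query genes, for a
    term annotating ``K`` of ``N`` universe genes.  ``fisher`` is the exact
    one-sided hypergeometric upper tail P(X >= k); ``ease`` recomputes the
    same tail after discarding one hit (k-1, floored at 0), so ease >= fisher
    always, and p = 1 whenever k <= 1.  ``k`` may be a scalar or array.
    """
    if method not in ("fisher", "ease"):
        raise ValueError(f"method must be fisher|ease, got {method!r}")
    k_arr = np.atleast_1d(np.asarray(k, dtype=int))
    if K > N or n > N or np.any(k_arr > np.minimum(n, K)) or np.any(k_arr < 0):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    shift = 1 if method == "fisher" else 2
    p = stats.hypergeom.sf(k_arr - shift, N, K, n)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if np.isscalar(k) or np.asarray(k).ndim == 0 else p


def bh_adjust(pvals) -> list:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    pvals = list(pvals)
    if not pvals:
        return []
    if any(p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(p) for p in adj]


def kappa_similarity(genes_a, genes_b, universe) -> float:
    """Cohen's kappa between two terms' gene-membership indicators.

    The 2x2 agreement table is taken over the universe; kappa is
    (observed - chance) / (1 - chance).  When chance agreement is 1 (both
    terms annotate everything, or nothing) kappa is defined as 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(genes_a) & universe
    b = set(genes_b) & universe
    n = len(universe)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = n - both - only_a - only_b
    po = (both + neither) / n
    pe = ((both + only_a) * (both + only_b) + (only_b + neither) * (only_a + neither)) / (
        n * n
    )
    if abs(1.0 - pe) < 1e-12:
        return 0.0
    return (po - pe) / (1.0 - pe)


def enrichment_score(member_pvals) -> float:
    """-log10 of the geometric mean of a cluster's raw member p-values."""
    pvals = np.asarray(list(member_pvals), dtype=float)
    if pvals.size == 0:
        raise ValueError("enrichment_score needs at least one p-value")
    if np.any(pvals < 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(pvals == 0):
        warnings.warn("p-value of 0 clamped to smallest positive float")
        pvals = np.maximum(pvals, np.finfo(float).tiny)
    return float(-np.mean(np.log10(pvals)))


@dataclasses.dataclass
class AnnotationCluster:
    member_terms: list  # term ids, deterministic order
    enrichment_score: float

    @property
    def significant(self) -> bool:
        return self.enrichment_score >= SIGNIFICANT_ENRICHMENT_SCORE


def cluster_terms(
    terms: list,
    term_pvals: dict,
    universe,
    kappa_min: float = 0.5,
    linkage_fraction: float = 0.5,
) -> list:
    """Greedy kappa-based functional annotation clustering.

    Every term seeds a group containing the terms whose kappa with it is at
    least ``kappa_min``; groups sharing at least ``linkage_fraction`` of the
    smaller group's members are merged iteratively to a fixpoint.  Each
    cluster scores -log10 geometric mean of member raw p-values; clusters
    return sorted descending by score (ties by first member id).
    """
    if not terms:
        return []
    universe = set(universe)
    ids = sorted(t.term_id for t in terms)
    by_id = {t.term_id: t for t in terms}

    groups = []
    for tid in ids:
        seed = by_id[tid]
        members = frozenset(
            other
            for other in ids
            if other == tid
            or kappa_similarity(
                seed.annotated_genes, by_id[other].annotated_genes, universe
            )
            >= kappa_min
        )
        groups.append(members)
    groups = sorted(set(groups), key=sorted)

    changed = True
    while changed:
        changed = False
        merged: list[frozenset] = []
        for grp in groups:
            for i, existing in enumerate(merged):
                shared = len(grp & existing)
                if shared and shared / min(len(grp), len(existing)) >= linkage_fraction:
                    merged[i] = existing | grp
                    changed = changed or merged[i] != existing
                    break
            else:
                merged.append(grp)
        if len(merged) != len(groups):
            changed = True
        groups = sorted(set(merged), key=sorted)

    clusters = [
        AnnotationCluster(
            member_terms=sorted(grp),
            enrichment_score=enrichment_score([term_pvals[t] for t in grp]),
        )
        for grp in groups
    ]
    clusters.sort(key=lambda c: (-c.enrichment_score, c.member_terms[0]))
    return clusters


@dataclasses.dataclass
class EnrichmentReport:
    """Per-term statistics plus kappa-clustered annotation groups."""

    terms: pd.DataFrame  # term_id, term_name, namespace, k, n, K, N, p_raw, p_bh
    clusters: list  # AnnotationCluster, sorted by score

    TERM_COLUMNS = ("term_id", "term_name", "namespace", "k", "n", "K", "N", "p_raw", "p_bh")

    def to_frame(self) -> pd.DataFrame:
        return self.terms[list(self.TERM_COLUMNS)].reset_index(drop=True)

    def cluster_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": i,
                "enrichment_score": round(c.enrichment_score, 6),
                "significant": c.significant,
                "member_terms": ",".join(c.member_terms),
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows, columns=["cluster_id", "enrichment_score", "significant", "member_terms"]
        )


def enrich_query(
    query,
    annotations: pd.DataFrame,
    universe=None,
    method: str = "ease",
    alpha: float = 0.05,
    kappa_min: float = 0.5,
    linkage_fraction: float = 0.5,
) -> EnrichmentReport:
    """Full enrichment analysis of a query gene set against an annotation table.

    The universe defaults to all genes appearing in the annotation table; an
    explicit background list may be supplied instead.  Terms with raw
    p < ``alpha`` enter the annotation clustering step.
    """
    if universe is None:
        universe = set(annotations["symbol"])
    else:
        universe = set(universe)
    query = set(query) & universe
    n, N = len(query), len(universe)

    terms = []
    for (tid, tname, ns), grp in annotations.groupby(
        ["term_id", "term_name", "namespace"], sort=True
    ):
        genes = frozenset(grp["symbol"]) & universe
        if genes:
            terms.append(TermRecord(tid, tname, ns, frozenset(genes)))

    rows = []
    for t in terms:
        K = len(t.annotated_genes)
        k = len(t.annotated_genes & query)
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "namespace": t.namespace,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_raw": term_pvalue(k, n, K, N, method=method),
            }
        )
    frame = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace",
                                        "k", "n", "K", "N", "p_raw"])
    frame["p_bh"] = bh_adjust(list(frame["p_raw"])) if len(frame) else []

    significant = [t for t in terms if frame.set_index("term_id")["p_raw"][t.term_id] < alpha]
    pvals = dict(zip(frame["term_id"], frame["p_raw"]))
    clusters = cluster_terms(
        significant, pvals, universe, kappa_min=kappa_min, linkage_fraction=linkage_fraction
    )
    return EnrichmentReport(terms=frame, clusters=clusters)
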