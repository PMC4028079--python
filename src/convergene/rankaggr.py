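"""Cumulative rank score aggregation across three genome-wide evidence types.

The method's core: each modality's clean gene table is ranked (rank 1 = best
gene under that modality's direction — highest linkage score, lowest
association weighted p, lowest expression adjusted p), the three-way symbol
intersection is taken, and each convergent gene receives the cumulative rank
score

    S_R = Rank_GWL + Rank_GWA + Rank_GWE

with ranks taken from the *full* modality tables, not re-ranked within the
intersection.  Convergent genes are then re-ranked ascending in S_R (lower
S_R = better final rank).  A concordance metric compares candidate sets from
a main and a replication analysis.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import pandas as pd

__all__ = [
    "MODALITIES",
    "RankedGeneTable",
    "ConvergenceResult",
    "rank_genes",
    "converge",
    "concordance",
]

MODALITIES = ("GWL", "GWA", "GWE")

#: Ranking direction per modality: linkage scores are higher-better,
#: association and expression p-values are lower-better.
DEFAULT_DIRECTIONS = {"GWL": "higher_better", "GWA": "lower_better", "GWE": "lower_better"}


@dataclasses.dataclass
class RankedGeneTable:
    """One modality's genes with scores and ordinal ranks 1..n.

    ``frame`` columns: symbol, score, rank.  Ranks are a permutation of 1..n
    and rank 1 is the best gene under ``direction``.
    """

    modality: str
    frame: pd.DataFrame
    direction: str

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"bad direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ranks(self) -> dict:
        return dict(zip(self.frame["symbol"], self.frame["rank"]))

    def to_frame(self) -> pd.DataFrame:
        return self.frame.sort_values("rank", kind="mergesort").reset_index(drop=True)


def rank_genes(table: pd.DataFrame, direction: str, modality: str) -> RankedGeneTable:
    """Assign ordinal ranks 1..n to a scored gene table.

    Ties in score break by ascending lexicographic symbol so the ranking is
    a deterministic permutation.  A NaN score is an error naming the gene.
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"bad direction {direction!r}")
    bad = [s for s, v in zip(table["symbol"], table["score"])
           if v is None or (isinstance(v, float) and math.isnan(v)) or not math.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite score for gene(s): {sorted(bad)}")
    ordered = table.sort_values(
        ["score", "symbol"],
        ascending=[direction == "lower_better", True],
        kind="mergesort",
    ).reset_index(drop=True)
    out = ordered[["symbol", "score"]].copy()
    out["rank"] = range(1, len(out) + 1)
    return RankedGeneTable(modality=modality, frame=out, direction=direction)


@dataclasses.dataclass
class ConvergenceResult:
    """Genes in the triple intersection with per-modality ranks and S_R.

    ``frame`` columns: symbol, rank_gwl, rank_gwa, rank_gwe,
    cumulative_rank_score, final_rank — sorted by final_rank.
    ``modality_sizes`` records the full-table sizes for provenance.
    """

    frame: pd.DataFrame
    modality_sizes: dict

    COLUMNS = (
        "symbol",
        "rank_gwl",
        "rank_gwa",
        "rank_gwe",
        "cumulative_rank_score",
        "final_rank",
    )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def symbols(self) -> list:
        return list(self.frame["symbol"])

    def top(self, k: int) -> list:
        return list(self.frame.nsmallest(k, "final_rank")["symbol"])

    def to_frame(self) -> pd.DataFrame:
        return self.frame[list(self.COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, modality_sizes: dict | None = None):
        frame = frame[list(cls.COLUMNS)].sort_values("final_rank").reset_index(drop=True)
        return cls(frame=frame, modality_sizes=dict(modality_sizes or {}))


def converge(*tables: RankedGeneTable) -> ConvergenceResult:
    """Intersect three ranked modality tables and score by cumulative rank.

    The three tables may be supplied in any order; they are identified by
    their ``modality`` labels, which must be exactly GWL, GWA, GWE.  S_R is
    the sum of a gene's ranks in the full tables; final ranks are ascending
    in S_R with lexicographic tie-break.  An empty intersection is valid
    (zero records, with a warning); an empty input table is an error.
    """
    by_mod = {t.modality: t for t in tables}
    if set(by_mod) != set(MODALITIES) or len(tables) != 3:
        raise ValueError(f"converge needs one table per modality {MODALITIES}")
    for mod in MODALITIES:
        if len(by_mod[mod]) == 0:
            raise ValueError(f"modality table {mod} is empty")

    ranks = {mod: by_mod[mod].ranks for mod in MODALITIES}
    common = set(ranks["GWL"]) & set(ranks["GWA"]) & set(ranks["GWE"])
    if not common:
        warnings.warn("empty triple intersection: no convergent genes")
    records = [
        {
            "symbol": sym,
            "rank_gwl": int(ranks["GWL"][sym]),
            "rank_gwa": int(ranks["GWA"][sym]),
            "rank_gwe": int(ranks["GWE"][sym]),
            "cumulative_rank_score": int(
                ranks["GWL"][sym] + ranks["GWA"][sym] + ranks["GWE"][sym]
            ),
        }
        for sym in sorted(common)
    ]
    frame = pd.DataFrame(
        records,
        columns=["symbol", "rank_gwl", "rank_gwa", "rank_gwe", "cumulative_rank_score"],
    )
    frame = frame.sort_values(
        ["cumulative_rank_score", "symbol"], kind="mergesort"
    ).reset_index(drop=True)
    frame["final_rank"] = range(1, len(frame) + 1)
    sizes = {mod: len(by_mod[mod]) for mod in MODALITIES}
    return ConvergenceResult(frame=frame, modality_sizes=sizes)


def concordance(set_a: set, set_b: set, denominator: str = "smaller") -> float:
    """Overlap fraction |A ∩ B| / |denominator set|, in [0, 1].

    ``denominator`` is ``"a"``, ``"b"``, ``"union"`` or ``"smaller"`` (the
    smaller of the two sets — the replication set in a replication analysis).
    Report as a percentage with one decimal via ``round(100 * value, 1)``.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("concordance requires two non-empty sets")
    denom = {
        "a": set_a,
        "b": set_b,
        "union": set_a | set_b,
        "smaller": set_a if len(set_a) <= len(set_b) else set_b,
    }.get(denominator)
    if denom is None:
        raise ValueError(f"bad denominator {denominator!r}")
    if not denom:
        raise ValueError("empty denominator set")
    return len(set_a & set_b) / len(denom)
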