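"""Modality-specific selection rules.

Each genome-wide evidence type (linkage, association, expression) arrives as
a raw table and leaves as a clean, scored one-row-per-gene table ready for
ranking.  Thresholds follow the study protocol: linkage regions kept at
LOD >= 2.0 or region p < 0.05; association SNPs kept at weighted p < 1e-3
with the per-gene minimum as the gene score; expression rows kept at
adjusted p < 0.05 with fold change >= 2.0 (up) or <= 0.5 (down) after
probe-set collapsing.  Gene-type exclusion removes pseudogenes, non-coding
classes, open reading frames, withdrawn entries, uncharacterized genes and
chromosome-X (Xp/Xq) genes, keeping active protein-coding genes only.
"""

from __future__ import annotations

import dataclasses
import re

import pandas as pd

from .iotables import LOCUS_TYPES

__all__ = [
    "DEFAULT_EXCLUDED_LOCUS_TYPES",
    "DEFAULT_EXCLUDED_BAND_PATTERNS",
    "FilterLog",
    "filter_gene_types",
    "select_linkage_genes",
    "select_association_genes",
    "collapse_probes",
    "filter_expression",
    "merge_regions",
    "region_specific_overlap",
]

#: Locus types removed before ranking (everything but protein_coding).
DEFAULT_EXCLUDED_LOCUS_TYPES = frozenset(
    {
        "pseudogene",
        "ncRNA",
        "antisense",
        "microRNA",
        "orf",
        "hypothetical",
        "uncharacterized",
        "withdrawn",
        "other",
    }
)

#: Cytogenetic band prefixes removed (chromosome X arms).
DEFAULT_EXCLUDED_BAND_PATTERNS = (r"^Xp", r"^Xq")


@dataclasses.dataclass
class FilterLog:
    """Removal log: rule name -> number of records it removed."""

    counts: dict

    @property
    def total_removed(self) -> int:
        return sum(self.counts.values())


def filter_gene_types(
    genes: pd.DataFrame,
    excluded_locus_types=DEFAULT_EXCLUDED_LOCUS_TYPES,
    excluded_band_patterns=DEFAULT_EXCLUDED_BAND_PATTERNS,
) -> tuple[pd.DataFrame, FilterLog]:
    """Keep active protein-coding genes outside the excluded bands.

    Rules are applied in order (locus type, status, band); a gene is counted
    against the first rule that removes it, so the log's per-rule counts sum
    to the number removed.
    """
    unknown = set(genes["locus_type"]) - LOCUS_TYPES
    if unknown:
        raise ValueError(f"unknown locus_type token(s): {sorted(unknown)}")

    band_res = [re.compile(p) for p in excluded_band_patterns]
    counts: dict[str, int] = {f"locus_type:{t}": 0 for t in sorted(excluded_locus_types)}
    counts["status:withdrawn"] = 0
    for pat in excluded_band_patterns:
        counts[f"band:{pat}"] = 0

    keep_mask = []
    for _, row in genes.iterrows():
        if row["locus_type"] in excluded_locus_types:
            counts[f"locus_type:{row['locus_type']}"] += 1
            keep_mask.append(False)
            continue
        if row["status"] != "active":
            counts["status:withdrawn"] += 1
            keep_mask.append(False)
            continue
        band = row.get("chromosome_band") or ""
        hit = next((p for p, cre in zip(excluded_band_patterns, band_res)
                    if cre.match(band)), None)
        if hit is not None:
            counts[f"band:{hit}"] += 1
            keep_mask.append(False)
            continue
        keep_mask.append(True)
    kept = genes[pd.Series(keep_mask, index=genes.index)].reset_index(drop=True)
    return kept, FilterLog({k: v for k, v in counts.items() if v})


def select_linkage_genes(
    regions: pd.DataFrame,
    gene_coords: pd.DataFrame,
    lod_min: float = 2.0,
    p_max: float = 0.05,
) -> set:
    """Genes overlapping any linkage region passing LOD/p thresholds.

    A region is kept when ``lod >= lod_min`` or ``p_value < p_max`` (missing
    values fail their clause).  A gene is selected when its half-open interval
    overlaps a kept region on the same chromosome by at least one base.
    """
    for _, r in regions.iterrows():
        if r["lod"] is None and r["p_value"] is None:
            raise ValueError(
                f"region {r['chromosome']}:{r['start_bp']}-{r['end_bp']} "
                "has neither lod nor p_value"
            )
    kept = regions[
        regions.apply(
            lambda r: (r["lod"] is not None and r["lod"] >= lod_min)
            or (r["p_value"] is not None and r["p_value"] < p_max),
            axis=1,
        )
    ]
    selected: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, r in kept.iterrows():
        by_chrom.setdefault(str(r["chromosome"]), []).append(
            (int(r["start_bp"]), int(r["end_bp"]))
        )
    for _, g in gene_coords.iterrows():
        for start, end in by_chrom.get(str(g["chromosome"]), ()):
            # half-open overlap: [a,b) meets [c,d) iff a < d and c < b
            if g["start_bp"] < end and start < g["end_bp"]:
                selected.add(g["symbol"])
                break
    return selected


def select_association_genes(snp_table: pd.DataFrame, p_max: float = 1e-3) -> pd.DataFrame:
    """Collapse a SNP association table to per-gene minimum weighted p.

    SNPs at ``weighted_p >= p_max`` (strict survival inequality) and SNPs
    without a mapped gene symbol are dropped; each surviving gene's score is
    the minimum weighted p over its SNPs.
    """
    kept = snp_table[(snp_table["weighted_p"] < p_max) & (snp_table["symbol"] != "")]
    if kept.empty:
        return pd.DataFrame(columns=["symbol", "score"])
    out = (
        kept.groupby("symbol", sort=True)["weighted_p"]
        .min()
        .reset_index()
        .rename(columns={"weighted_p": "score"})
    )
    return out


def _direction(fc: float) -> int:
    if fc > 1.0:
        return 1
    if fc < 1.0:
        return -1
    return 0


def collapse_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple probe sets per gene within one brain region.

    Singleton genes pass through.  Multi-probe genes whose probes agree in
    direction (all up or all down relative to fold change 1) are represented
    by their highest-variance probe; genes with discordant directions are
    removed entirely.  Fold change exactly 1 carries no direction: a gene
    mixing FC=1 probes with directional probes is treated as discordant,
    while a gene whose probes are all exactly 1 is kept (trivially
    concordant).  Variance ties break by probe_id for determinism.
    """
    regions = set(probes["region"])
    if len(regions) > 1:
        raise ValueError(f"collapse_probes expects a single region, got {sorted(regions)}")
    rows = []
    for _, grp in probes.groupby("symbol", sort=True):
        if len(grp) == 1:
            rows.append(grp.iloc[0])
            continue
        dirs = {_direction(fc) for fc in grp["fold_change"]}
        if len(dirs) > 1:
            continue  # discordant -> gene removed
        best = grp.sort_values(
            ["variance", "probe_id"], ascending=[False, True], kind="mergesort"
        ).iloc[0]
        rows.append(best)
    if not rows:
        return probes.iloc[0:0].copy()
    return pd.DataFrame(rows).reset_index(drop=True)


def filter_expression(
    rows: pd.DataFrame,
    adjp_max: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> pd.DataFrame:
    """Keep rows with adjusted p < adjp_max and |effect| past the FC gates.

    Fold-change bounds are inclusive (>= fc_up for up-regulated, <= fc_down
    for down-regulated); the adjusted-p cut is strict.
    """
    mask = (rows["adjusted_p"] < adjp_max) & (
        (rows["fold_change"] >= fc_up) | (rows["fold_change"] <= fc_down)
    )
    return rows[mask].reset_index(drop=True)


def merge_regions(per_region: dict) -> pd.DataFrame:
    """Merge per-region filtered expression tables into one scored gene table.

    The union of gene symbols is taken; each gene's score is the minimum
    adjusted p across the regions in which it survived, and the contributing
    region set is recorded (comma-joined, sorted).
    """
    if not per_region:
        raise ValueError("merge_regions: empty region map")
    best: dict[str, float] = {}
    regions_of: dict[str, set] = {}
    for region in sorted(per_region):
        table = per_region[region]
        for _, row in table.iterrows():
            sym = row["symbol"]
            p = float(row["adjusted_p"])
            if sym not in best or p < best[sym]:
                best[sym] = p
            regions_of.setdefault(sym, set()).add(region)
    out = pd.DataFrame(
        {
            "symbol": sorted(best),
            "score": [best[s] for s in sorted(best)],
            "regions": [",".join(sorted(regions_of[s])) for s in sorted(best)],
        }
    )
    return out


def region_specific_overlap(
    per_region_genes: dict, gwl_set: set, gwa_set: set
) -> dict:
    """Per-region triple intersection with the linkage and association sets.

    "Region-specific" candidates are computed independently per region,
    before any cross-region deduplication: each region's surviving expression
    genes intersected with the full linkage and association repertoires.
    """
    return {
        region: set(genes) & set(gwl_set) & set(gwa_set)
        for region, genes in per_region_genes.items()
    }
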