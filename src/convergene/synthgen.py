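"""Seeded synthetic-study generator with recorded ground truth.

Emulates the statistical shape of a three-modality genomic-convergence study
— a gene universe with a realistic mix of excluded locus types, linkage
regions harbouring the linkage survivors, a SNP association table, per-region
expression probe tables with probe multiplicity and discordance, an
evidence-counted interaction edge list with planted dense modules,
localization and annotation tables with planted enriched terms, and CSF and
plasma fluid lists with a planted Venn structure — so the entire pipeline is
testable without any external download.

Planting model: a set of "true" convergent genes is guaranteed to survive
every modality's filters, and their scores are drawn with a rank advantage:
with advantage ``a``, a planted gene's score quantile is distributed
Beta(1, a) toward the good end of the scale (``a = 1`` means no advantage,
planted genes are exchangeable with null survivors).  The pipeline consumes
only score order, so planting in rank space is the minimal sufficient model.

One integer seed drives everything through a numpy SeedSequence spawned into
per-stage child generators, so the whole bundle is byte-identical per seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import iotables

__all__ = ["SynthConfig", "TruthRecord", "generate_study", "generate_modality_tables",
           "evaluate_recovery", "BRAIN_REGIONS"]

BRAIN_REGIONS = ("EC", "HIP", "MTG", "PC", "SFG", "VCX")

_EXCLUDED_TYPE_WEIGHTS = {
    "pseudogene": 0.30,
    "ncRNA": 0.20,
    "hypothetical": 0.12,
    "orf": 0.10,
    "antisense": 0.08,
    "microRNA": 0.08,
    "uncharacterized": 0.12,
}


@dataclasses.dataclass
class SynthConfig:
    """Study conditions for the synthetic bundle.

    Defaults describe a desk-scale study: a 2,000-gene universe with 30
    planted convergent genes, modality survivor tables of 600/400/800 genes,
    a strong planted rank advantage, six brain regions, six dense network
    modules and five enriched annotation terms.
    """

    seed: int = 7
    n_genes: int = 2000
    n_planted: int = 30
    modality_sizes: dict = dataclasses.field(
        default_factory=lambda: {"GWL": 600, "GWA": 400, "GWE": 800}
    )
    planted_rank_advantage: float = 50.0
    excluded_fraction: float = 0.15  # excluded locus types
    withdrawn_fraction: float = 0.02
    x_fraction: float = 0.03  # genes on Xp/Xq bands
    n_regions: int = 6
    probe_multiplicity_dist: dict = dataclasses.field(
        default_factory=lambda: {1: 0.60, 2: 0.25, 3: 0.10, 4: 0.05}
    )
    discordance_rate: float = 0.10
    network_modules: int = 6
    module_size: int = 8
    module_density: float = 0.8
    background_density: float = 0.01
    evidence_dist: dict = dataclasses.field(
        default_factory=lambda: {1: 0.45, 2: 0.35, 3: 0.15, 4: 0.05}
    )
    n_terms: int = 100
    n_planted_terms: int = 5
    planted_term_overlap: float = 0.6
    fluid_overlap_counts: dict = dataclasses.field(
        default_factory=lambda: {
            "triple": 3,
            "candidates_csf": 5,
            "candidates_plasma": 4,
            "csf_plasma": 20,
            "csf_only": 50,
            "plasma_only": 60,
        }
    )

    def validate(self) -> None:
        if self.n_planted < 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        n_eligible = self._n_eligible()
        for mod, size in self.modality_sizes.items():
            if self.n_planted > size:
                raise ValueError(
                    f"infeasible config: n_planted {self.n_planted} exceeds "
                    f"{mod} modality size {size}"
                )
            if size > n_eligible:
                raise ValueError(
                    f"infeasible config: {mod} size {size} exceeds the "
                    f"~{n_eligible} eligible protein-coding genes"
                )
        if not (0 < self.module_density <= 1) or not (0 < self.background_density <= 1):
            raise ValueError("densities must lie in (0, 1]")
        if self.module_density <= self.background_density:
            raise ValueError("module_density must exceed background_density")
        if self.planted_rank_advantage < 1:
            raise ValueError("planted_rank_advantage must be >= 1")

    def _n_eligible(self) -> int:
        return int(
            self.n_genes
            * (1 - self.excluded_fraction - self.withdrawn_fraction - self.x_fraction)
        )


@dataclasses.dataclass
class TruthRecord:
    """Every planted entity, for downstream recovery checks."""

    planted_genes: list
    module_members: dict  # module id -> sorted member list
    fallback_seeds: list  # planted genes wired with evidence-1 edges only
    enriched_terms: list
    fluid_triple: list
    per_region_planted: dict  # region -> planted genes surviving there

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "planted_gene", "key": "", "value": g} for g in self.planted_genes]
        rows += [
            {"kind": "module_member", "key": str(m), "value": g}
            for m, members in sorted(self.module_members.items())
            for g in members
        ]
        rows += [{"kind": "fallback_seed", "key": "", "value": g} for g in self.fallback_seeds]
        rows += [{"kind": "enriched_term", "key": "", "value": t} for t in self.enriched_terms]
        rows += [{"kind": "fluid_triple", "key": "", "value": g} for g in self.fluid_triple]
        rows += [
            {"kind": "region_planted", "key": r, "value": g}
            for r, genes in sorted(self.per_region_planted.items())
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["kind", "key", "value"])


def _child_rngs(seed: int, n: int = 8) -> list:
    """Documented seed-splitting scheme: SeedSequence(seed).spawn per stage."""
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def _advantage_quantile(rng, size, advantage):
    """Score quantiles toward the good end: Beta(1, advantage)."""
    return rng.beta(1.0, advantage, size=size)


# ---------------------------------------------------------------------------
# stage generators


def _gen_genes(cfg: SynthConfig, rng) -> dict:
    n = cfg.n_genes
    symbols = [f"GENE{i:05d}" for i in range(1, n + 1)]
    order = rng.permutation(n)

    n_excl = int(cfg.excluded_fraction * n)
    n_withdrawn = int(cfg.withdrawn_fraction * n)
    n_x = int(cfg.x_fraction * n)

    locus = {}
    status = {}
    excl_types = list(_EXCLUDED_TYPE_WEIGHTS)
    excl_p = np.array([_EXCLUDED_TYPE_WEIGHTS[t] for t in excl_types])
    excl_p = excl_p / excl_p.sum()
    cursor = 0
    for idx in order[cursor : cursor + n_excl]:
        locus[symbols[idx]] = excl_types[rng.choice(len(excl_types), p=excl_p)]
        status[symbols[idx]] = "active"
    cursor += n_excl
    for idx in order[cursor : cursor + n_withdrawn]:
        locus[symbols[idx]] = "withdrawn"
        status[symbols[idx]] = "withdrawn"
    cursor += n_withdrawn
    x_genes = [symbols[idx] for idx in order[cursor : cursor + n_x]]
    cursor += n_x
    for s in symbols:
        locus.setdefault(s, "protein_coding")
        status.setdefault(s, "active")

    chrom = {}
    band = {}
    for s in symbols:
        if s in x_genes:
            chrom[s] = "X"
            arm = "p" if rng.random() < 0.5 else "q"
            band[s] = f"X{arm}{rng.integers(11, 28)}.{rng.integers(1, 4)}"
        else:
            c = int(rng.integers(1, 23))
            chrom[s] = str(c)
            arm = "p" if rng.random() < 0.5 else "q"
            band[s] = f"{c}{arm}{rng.integers(11, 37)}.{rng.integers(1, 4)}"

    eligible = [
        s
        for s in symbols
        if locus[s] == "protein_coding" and status[s] == "active" and chrom[s] != "X"
    ]
    metadata = pd.DataFrame(
        {
            "symbol": symbols,
            "hgnc_id": [f"HGNC:{10000 + i}" for i in range(1, n + 1)],
            "locus_type": [locus[s] for s in symbols],
            "chromosome_band": [band[s] for s in symbols],
            "status": [status[s] for s in symbols],
        }
    )
    return {"metadata": metadata, "chrom": chrom, "eligible": eligible, "symbols": symbols}


def _gen_modality_scores(cfg: SynthConfig, genes: dict, rng) -> dict:
    """Choose survivor sets (planted always included) and draw scores."""
    eligible = genes["eligible"]
    planted = sorted(rng.choice(eligible, size=cfg.n_planted, replace=False).tolist())
    rest = sorted(set(eligible) - set(planted))
    out = {"planted": planted, "tables": {}}

    a = cfg.planted_rank_advantage
    for mod, size in sorted(cfg.modality_sizes.items()):
        extra = sorted(
            rng.choice(rest, size=size - cfg.n_planted, replace=False).tolist()
        )
        members = planted + extra
        if mod == "GWL":  # higher-better GeneWanderer-style scores
            null_scores = rng.uniform(0.0, 1.0, size=len(extra))
            planted_scores = 1.0 - _advantage_quantile(rng, cfg.n_planted, a)
        elif mod == "GWA":  # weighted p below the 1e-3 survival cut
            null_scores = rng.uniform(0.0, 1e-3, size=len(extra))
            planted_scores = 1e-3 * _advantage_quantile(rng, cfg.n_planted, a)
        else:  # GWE: adjusted p below 0.05
            null_scores = rng.uniform(0.0, 0.05, size=len(extra))
            planted_scores = 0.05 * _advantage_quantile(rng, cfg.n_planted, a)
        scores = np.concatenate([planted_scores, null_scores])
        table = pd.DataFrame({"symbol": members, "score": scores})
        out["tables"][mod] = table.sort_values("symbol", kind="mergesort").reset_index(
            drop=True
        )
    return out


def _gen_coordinates_and_regions(cfg: SynthConfig, genes: dict, gwl_table, rng):
    """Lay out gene intervals so linkage regions select exactly the GWL set.

    Survivor genes (plus any excluded-type genes that the gene-type filter
    will remove anyway) are placed in one contiguous block per chromosome and
    covered by a region passing the LOD/p thresholds; decoy regions failing
    both thresholds cover part of the remainder.
    """
    gwl_set = set(gwl_table["symbol"])
    chrom_of = genes["chrom"]
    by_chrom: dict[str, list] = {}
    for s in genes["symbols"]:
        by_chrom.setdefault(chrom_of[s], []).append(s)

    coords_rows = []
    region_rows = []
    gene_len = 20_000
    gap = 5_000
    for chrom in sorted(by_chrom):
        members = by_chrom[chrom]
        in_block = [s for s in members if s in gwl_set]
        out_block = [s for s in members if s not in gwl_set]
        rng.shuffle(out_block)
        # excluded-type genes may ride inside the linkage block: the
        # downstream gene-type filter removes them, not the region filter
        passengers = [
            s
            for s in out_block
            if s not in genes["eligible"]
        ][: max(1, len(in_block) // 10)] if in_block else []
        out_block = [s for s in out_block if s not in passengers]
        block = sorted(in_block + passengers)
        rng.shuffle(block)

        split = len(out_block) // 2
        layout = out_block[:split] + block + out_block[split:]
        pos = 1_000_000
        spans = {}
        for s in layout:
            coords_rows.append(
                {"chromosome": chrom, "start_bp": pos, "end_bp": pos + gene_len, "symbol": s}
            )
            spans[s] = (pos, pos + gene_len)
            pos += gene_len + gap
        if block:
            start = min(spans[s][0] for s in block)
            end = max(spans[s][1] for s in block)
            if rng.random() < 0.5:
                region_rows.append(
                    {"chromosome": chrom, "start_bp": start - 1000, "end_bp": end + 1000,
                     "lod": round(float(rng.uniform(2.0, 5.0)), 3), "p_value": None}
                )
            else:
                region_rows.append(
                    {"chromosome": chrom, "start_bp": start - 1000, "end_bp": end + 1000,
                     "lod": None, "p_value": round(float(rng.uniform(1e-4, 0.049)), 6)}
                )
        if out_block[:split]:
            decoy = out_block[: max(1, split // 3)]
            dstart = min(spans[s][0] for s in decoy)
            dend = max(spans[s][1] for s in decoy)
            region_rows.append(
                {"chromosome": chrom, "start_bp": dstart, "end_bp": dend,
                 "lod": round(float(rng.uniform(0.1, 1.9)), 3),
                 "p_value": round(float(rng.uniform(0.10, 0.9)), 4)}
            )
    coords = pd.DataFrame(coords_rows, columns=["chromosome", "start_bp", "end_bp", "symbol"])
    regions = pd.DataFrame(region_rows, columns=["chromosome", "start_bp", "end_bp", "lod", "p_value"])
    return coords, regions


def _gen_snp_table(cfg: SynthConfig, genes: dict, gwa_table, rng) -> pd.DataFrame:
    rows = []
    snp_counter = 1

    def add(symbol, p):
        nonlocal snp_counter
        rows.append({"snp_id": f"rs{snp_counter:06d}", "symbol": symbol,
                     "weighted_p": float(p)})
        snp_counter += 1

    for _, row in gwa_table.iterrows():
        add(row["symbol"], row["score"])  # the gene's minimum weighted p
        for _ in range(int(rng.integers(0, 3))):
            add(row["symbol"], rng.uniform(row["score"], 1.0))
    survivors = set(gwa_table["symbol"])
    nulls = [s for s in genes["symbols"] if s not in survivors]
    for s in rng.choice(nulls, size=min(300, len(nulls)), replace=False):
        add(s, rng.uniform(1e-3, 1.0))  # fails the p < 1e-3 cut
    for _ in range(20):
        add("", rng.uniform(0.0, 1e-4))  # unmapped SNPs, dropped regardless of p
    df = pd.DataFrame(rows, columns=["snp_id", "symbol", "weighted_p"])
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31 - 1))).reset_index(
        drop=True
    )


def _multiplicity(cfg: SynthConfig, rng) -> int:
    ks = sorted(cfg.probe_multiplicity_dist)
    ps = np.array([cfg.probe_multiplicity_dist[k] for k in ks], dtype=float)
    return int(np.array(ks)[rng.choice(len(ks), p=ps / ps.sum())])


def _probe_rows(symbol, region, direction, best_fc, best_p, m, rng, probe_ids):
    """m probes for one gene/region; the highest-variance probe is the keeper."""
    variances = np.sort(rng.uniform(0.1, 5.0, size=m))[::-1]
    rows = []
    for j in range(m):
        if j == 0:
            fc, adjp = best_fc, best_p
        else:
            fc = (1.0 + rng.exponential(0.8)) if direction > 0 else rng.uniform(0.3, 1.0)
            adjp = rng.uniform(0.0, 1.0)
        rows.append(
            {"probe_id": next(probe_ids), "symbol": symbol, "fold_change": round(float(fc), 4),
             "adjusted_p": float(adjp), "variance": round(float(variances[j]), 4),
             "region": region}
        )
    return rows


def _gen_expression(cfg: SynthConfig, genes: dict, gwe_table, rng):
    regions = list(BRAIN_REGIONS[: cfg.n_regions]) or [
        f"R{i}" for i in range(1, cfg.n_regions + 1)
    ]
    counter = iter(range(1, 10**7))
    probe_ids = (f"PS{i:06d}_at" for i in counter)

    rows = []
    per_region_survivors: dict[str, set] = {r: set() for r in regions}
    for _, grec in gwe_table.iterrows():
        sym, best_p = grec["symbol"], float(grec["score"])
        member_regions = [r for r in regions if rng.random() < 0.35]
        if not member_regions:
            member_regions = [regions[int(rng.integers(0, len(regions)))]]
        best_region = member_regions[int(rng.integers(0, len(member_regions)))]
        direction = 1 if rng.random() < 0.5 else -1
        for r in member_regions:
            per_region_survivors[r].add(sym)
            fc = (2.0 + rng.exponential(1.5)) if direction > 0 else rng.uniform(0.05, 0.5)
            adjp = best_p if r == best_region else rng.uniform(best_p, 0.05)
            rows += _probe_rows(sym, r, direction, fc, adjp,
                                _multiplicity(cfg, rng), rng, probe_ids)

    # null genes: concordant-but-failing rows, plus discordant multi-probe genes
    survivors = set(gwe_table["symbol"])
    nulls = [s for s in genes["symbols"] if s not in survivors]
    n_null = min(400, len(nulls))
    chosen = rng.choice(nulls, size=n_null, replace=False)
    for sym in chosen:
        r = regions[int(rng.integers(0, len(regions)))]
        if rng.random() < cfg.discordance_rate:
            # discordant: passing values in both directions -> dropped at collapse
            rows += _probe_rows(sym, r, 1, 2.0 + rng.exponential(1.0),
                                rng.uniform(0, 0.05), 1, rng, probe_ids)
            rows += _probe_rows(sym, r, -1, rng.uniform(0.05, 0.5),
                                rng.uniform(0, 0.05), 1, rng, probe_ids)
        else:
            direction = 1 if rng.random() < 0.5 else -1
            if rng.random() < 0.5:  # fails fold-change gate
                fc = rng.uniform(1.05, 1.95) if direction > 0 else rng.uniform(0.55, 0.95)
                adjp = rng.uniform(0.0, 0.05)
            else:  # fails adjusted-p gate
                fc = (2.0 + rng.exponential(1.0)) if direction > 0 else rng.uniform(0.05, 0.5)
                adjp = rng.uniform(0.05, 1.0)
            rows += _probe_rows(sym, r, direction, fc, adjp,
                                _multiplicity(cfg, rng), rng, probe_ids)
    df = pd.DataFrame(
        rows,
        columns=["probe_id", "symbol", "fold_change", "adjusted_p", "variance", "region"],
    )
    return df, per_region_survivors


def _gen_network(cfg: SynthConfig, genes: dict, planted: list, rng):
    eligible = [s for s in genes["eligible"] if s not in set(planted)]
    module_members: dict[int, list] = {}
    pair_ev: dict[tuple, int] = {}

    ev_ks = sorted(cfg.evidence_dist)
    ev_ps = np.array([cfg.evidence_dist[k] for k in ev_ks], dtype=float)
    ev_ps = ev_ps / ev_ps.sum()

    def background_evidence():
        return int(np.array(ev_ks)[rng.choice(len(ev_ks), p=ev_ps)])

    def put(a, b, ev):
        if a == b:
            return
        key = (a, b) if a <= b else (b, a)
        pair_ev[key] = max(pair_ev.get(key, 0), int(ev))

    # distribute planted genes across modules, pad with eligible partners
    fallback_seeds = sorted(planted)[: max(0, min(3, len(planted)))]
    module_planted = [g for g in planted if g not in fallback_seeds]
    pad_pool = list(rng.permutation(eligible))
    for m in range(cfg.network_modules):
        core = module_planted[m :: cfg.network_modules]
        pad = [pad_pool.pop() for _ in range(max(0, cfg.module_size - len(core)))]
        members = sorted(core + pad)
        module_members[m] = members
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if rng.random() < cfg.module_density:
                    put(a, b, int(rng.integers(2, 5)))
        # guarantee connectivity of planted members inside the module
        for g in core:
            partner = next(x for x in members if x != g)
            put(g, partner, 2)

    # fallback seeds: only single-validation edges
    for g in fallback_seeds:
        for _ in range(int(rng.integers(1, 3))):
            put(g, pad_pool.pop(), 1)

    # background edges incident to the planted seeds
    all_nodes = sorted({g for mem in module_members.values() for g in mem} | set(planted))
    n_bg = int(cfg.background_density * len(all_nodes) * len(eligible) * 0.05) + 20
    for _ in range(n_bg):
        a = all_nodes[int(rng.integers(0, len(all_nodes)))]
        b = eligible[int(rng.integers(0, len(eligible)))]
        key = (a, b) if a <= b else (b, a)
        if key in pair_ev or a in fallback_seeds or b in fallback_seeds:
            continue
        put(a, b, background_evidence())

    rows = [
        {"protein_a": a, "protein_b": b, "evidence_count": ev}
        for (a, b), ev in sorted(pair_ev.items())
    ]
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "evidence_count"])
    edges = edges.sample(
        frac=1.0, random_state=int(rng.integers(0, 2**31 - 1))
    ).reset_index(drop=True)

    nodes = sorted({*edges["protein_a"], *edges["protein_b"]})
    loc_rows = [
        {"protein": nnode, "compartment": iotables.COMPARTMENTS[
            int(rng.integers(0, len(iotables.COMPARTMENTS)))]}
        for nnode in nodes
        if rng.random() < 0.9
    ]
    localization = pd.DataFrame(loc_rows, columns=["protein", "compartment"])
    return edges, localization, module_members, fallback_seeds


def _gen_annotations(cfg: SynthConfig, genes: dict, planted: list, rng):
    eligible = genes["eligible"]
    universe = sorted(
        set(planted)
        | set(rng.choice(eligible, size=min(800, len(eligible)), replace=False).tolist())
    )
    namespaces = ("BP", "MF", "CC")
    rows = []
    enriched = []
    for t in range(1, cfg.n_terms + 1):
        tid = f"TERM:{t:04d}"
        ns = namespaces[t % 3]
        if t <= cfg.n_planted_terms:
            enriched.append(tid)
            n_pl = max(2, int(cfg.planted_term_overlap * len(planted)))
            members = set(rng.choice(planted, size=min(n_pl, len(planted)),
                                     replace=False).tolist())
            members |= set(rng.choice(universe, size=int(rng.integers(3, 10)),
                                      replace=False).tolist())
        else:
            size = int(rng.integers(5, 50))
            members = set(rng.choice(universe, size=size, replace=False).tolist())
        for g in sorted(members):
            rows.append({"term_id": tid, "term_name": f"synthetic process {t}",
                         "namespace": ns, "symbol": g})
    annotations = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace", "symbol"])
    return annotations, enriched, universe


def _gen_fluids(cfg: SynthConfig, genes: dict, planted: list, rng):
    # planted-dependent Venn counts clamp to the planted genes available,
    # so sparse configs (few or zero planted genes) remain generable
    counts = cfg.fluid_overlap_counts
    planted_pool = list(planted)
    rng.shuffle(planted_pool)
    triple = sorted(planted_pool[: counts.get("triple", 0)])
    cursor = len(triple)
    cand_csf = planted_pool[cursor : cursor + counts.get("candidates_csf", 0)]
    cursor += len(cand_csf)
    cand_plasma = planted_pool[cursor : cursor + counts.get("candidates_plasma", 0)]

    others = [s for s in genes["symbols"] if s not in set(planted)]
    rng.shuffle(others)
    need = counts.get("csf_plasma", 0) + counts.get("csf_only", 0) + counts.get("plasma_only", 0)
    pool = others[:need]
    csf_plasma = pool[: counts.get("csf_plasma", 0)]
    csf_only = pool[len(csf_plasma) : len(csf_plasma) + counts.get("csf_only", 0)]
    plasma_only = pool[len(csf_plasma) + len(csf_only) :]

    csf = set(triple) | set(cand_csf) | set(csf_plasma) | set(csf_only)
    plasma = set(triple) | set(cand_plasma) | set(csf_plasma) | set(plasma_only)
    return csf, plasma, triple


# ---------------------------------------------------------------------------
# public API


def generate_modality_tables(config: SynthConfig):
    """Fast path: the three scored survivor tables plus the planted genes.

    Uses the same per-stage child generators as :func:`generate_study`, so
    for a given seed the tables match the full bundle's post-filter tables.
    """
    config.validate()
    rngs = _child_rngs(config.seed)
    genes = _gen_genes(config, rngs[0])
    modal = _gen_modality_scores(config, genes, rngs[1])
    return modal["tables"], modal["planted"]


def generate_study(config: SynthConfig, out_dir=None):
    """Generate the full input bundle and its TruthRecord.

    Returns ``(bundle, truth)`` where ``bundle`` maps table names to
    DataFrames (and the fluid lists to sets).  If ``out_dir`` is given every
    table is also written as TSV (fluid lists as one-id-per-line text), fully
    deterministically for a given seed.
    """
    config.validate()
    rngs = _child_rngs(config.seed)
    genes = _gen_genes(config, rngs[0])
    modal = _gen_modality_scores(config, genes, rngs[1])
    planted = modal["planted"]

    coords, regions = _gen_coordinates_and_regions(
        config, genes, modal["tables"]["GWL"], rngs[2]
    )
    snp_table = _gen_snp_table(config, genes, modal["tables"]["GWA"], rngs[3])
    probes, per_region = _gen_expression(config, genes, modal["tables"]["GWE"], rngs[4])
    edges, localization, modules, fallback_seeds = _gen_network(
        config, genes, planted, rngs[5]
    )
    annotations, enriched_terms, _ = _gen_annotations(config, genes, planted, rngs[6])
    csf, plasma, fluid_triple = _gen_fluids(config, genes, planted, rngs[7])

    truth = TruthRecord(
        planted_genes=list(planted),
        module_members={m: list(v) for m, v in modules.items()},
        fallback_seeds=list(fallback_seeds),
        enriched_terms=list(enriched_terms),
        fluid_triple=list(fluid_triple),
        per_region_planted={
            r: sorted(set(per_region[r]) & set(planted)) for r in per_region
        },
    )
    bundle = {
        "gene_metadata": genes["metadata"],
        "gene_coords": coords,
        "linkage_regions": regions,
        "gwl_scores": modal["tables"]["GWL"],
        "snp_assoc": snp_table,
        "expression_probes": probes,
        "edges": edges,
        "localization": localization,
        "annotations": annotations,
        "csf": csf,
        "plasma": plasma,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "gene_metadata",
            "gene_coords",
            "linkage_regions",
            "gwl_scores",
            "snp_assoc",
            "expression_probes",
            "edges",
            "localization",
            "annotations",
        ):
            iotables.write_table(bundle[name], out / f"{name}.tsv")
        iotables.write_id_list(csf, out / "csf.txt")
        iotables.write_id_list(plasma, out / "plasma.txt")
        iotables.write_table(truth.to_frame(), out / "truth.tsv")
    return bundle, truth


def evaluate_recovery(result, truth: TruthRecord, top_k: int) -> float:
    """Fraction of planted genes within the top_k final ranks.

    Zero planted genes yields 0.0 by convention; ``top_k`` larger than the
    result is an error.
    """
    if top_k > len(result):
        raise ValueError(f"top_k {top_k} exceeds result size {len(result)}")
    if not truth.planted_genes:
        return 0.0
    top = set(result.top(top_k))
    return len(top & set(truth.planted_genes)) / len(truth.planted_genes)
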