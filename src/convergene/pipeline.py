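"""End-to-end pipeline: prefilter -> converge -> network -> enrich -> biomarker.

Driven by a single YAML config mapping input paths and thresholds; every
exclusion rule's input/output counts are logged so the whole filtering
funnel is auditable.  All outputs are deterministic: re-running with the
same inputs and config produces byte-identical report files (the run log
records counts and parameters, never wall-clock times).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import biomarker, enrich, iotables, netmod, prefilter, rankaggr

logger = logging.getLogger("convergene")

REQUIRED_INPUTS = (
    "gene_metadata",
    "gene_coords",
    "linkage_regions",
    "gwl_scores",
    "snp_assoc",
    "expression_probes",
    "edges",
    "localization",
    "annotations",
    "csf_list",
    "plasma_list",
)

DEFAULT_PARAMS = {
    "lod_min": 2.0,
    "region_p_max": 0.05,
    "gwa_p_max": 1e-3,
    "adjp_max": 0.05,
    "fc_up": 2.0,
    "fc_down": 0.5,
    "log2_fold_change": False,
    "mcl_inflation": 2.0,
    "mcl_pruning_threshold": 1e-5,
    "min_cluster_size": 5,
    "enrich_method": "ease",
    "enrich_alpha": 0.05,
    "kappa_min": 0.5,
    "linkage_fraction": 0.5,
}

DEFAULT_STAGES = {
    "convergence": True,
    "regions": True,
    "network": True,
    "cluster": True,
    "enrich": True,
    "biomarker": True,
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _resolve_inputs(cfg: dict, base: Path) -> dict:
    inputs = cfg.get("inputs", {})
    resolved = {}
    need_primary = cfg.get("stages", {}).get("convergence", True) and not cfg.get(
        "intermediates", {}
    ).get("convergence")
    for key in REQUIRED_INPUTS:
        if key not in inputs:
            primary = key not in ("edges", "localization", "annotations", "csf_list", "plasma_list")
            if primary and not need_primary:
                continue
            raise ConfigError(f"missing required input in config: {key}")
        p = Path(inputs[key])
        resolved[key] = p if p.is_absolute() else base / p
    return resolved


def run_pipeline(config_path, out_dir) -> dict:
    """Run all enabled stages; write reports, run log and MANIFEST.

    Returns the run log dict.  On a stage failure the exception propagates
    after partial outputs and a MANIFEST flagging incompleteness are written.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    base = config_path.parent
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    stages = dict(DEFAULT_STAGES)
    stages.update(cfg.get("stages", {}))
    intermediates = cfg.get("intermediates", {})

    run_log: dict = {"params": params, "stages": {}}
    manifest: list[str] = []
    complete = False

    def emit(name: str, obj) -> None:
        iotables.write_table(obj, out / name)
        manifest.append(name)

    try:
        paths = _resolve_inputs(cfg, base)

        if intermediates.get("convergence"):
            conv_path = Path(intermediates["convergence"])
            conv_path = conv_path if conv_path.is_absolute() else base / conv_path
            import pandas as pd

            conv = rankaggr.ConvergenceResult.from_frame(
                pd.read_csv(conv_path, sep="\t")
            )
            logger.info("convergence stage skipped; loaded %d genes from %s",
                        len(conv), conv_path)
            run_log["stages"]["convergence"] = {"skipped": True, "n_genes": len(conv)}
            per_region_filtered = None
        else:
            conv, per_region_filtered = _run_convergence(paths, params, run_log, emit)

        seeds = set(conv.symbols)

        if stages.get("regions") and per_region_filtered is not None:
            gwl_set = set(run_log["stages"]["gwl"]["symbols"])
            gwa_set = set(run_log["stages"]["gwa"]["symbols"])
            spec_map = prefilter.region_specific_overlap(
                {r: set(t["symbol"]) for r, t in per_region_filtered.items()},
                gwl_set,
                gwa_set,
            )
            import pandas as pd

            emit(
                "region_specific.tsv",
                pd.DataFrame(
                    [
                        {"region": r, "n_genes": len(g), "genes": ",".join(sorted(g))}
                        for r, g in sorted(spec_map.items())
                    ],
                    columns=["region", "n_genes", "genes"],
                ),
            )
            run_log["stages"]["regions"] = {
                "counts": {r: len(g) for r, g in sorted(spec_map.items())}
            }
        # symbols lists were only needed for the region report
        for key in ("gwl", "gwa"):
            if key in run_log["stages"]:
                run_log["stages"][key].pop("symbols", None)

        network = None
        if stages.get("network"):
            edges = iotables.read_table(paths["edges"], "edges")
            localization = iotables.read_table(paths["localization"], "localization")
            network = netmod.build_network(seeds, edges)
            loc_map: dict = {}
            for _, row in localization.iterrows():
                loc_map.setdefault(row["protein"], []).append(row["compartment"])
            netmod.assign_layers(network, loc_map)
            emit("network_edges.tsv", network.edge_frame())
            run_log["stages"]["network"] = {
                "n_input_edges": int(len(edges)),
                "n_nodes": network.n_nodes,
                "n_edges": network.n_edges,
                "layer_counts": network.layer_counts(),
            }
            logger.info("network: %d nodes, %d edges", network.n_nodes, network.n_edges)

        if stages.get("cluster") and network is not None:
            mcl_params = netmod.MCLParams(
                inflation=float(params["mcl_inflation"]),
                pruning_threshold=float(params["mcl_pruning_threshold"]),
            )
            clusters = netmod.mcl_cluster(network, mcl_params)
            clusters.min_significant_size = int(params["min_cluster_size"])
            emit("clusters.tsv", clusters)
            run_log["stages"]["cluster"] = {
                "n_clusters": len(clusters),
                "n_significant": len(clusters.significant),
                "hubs": sorted(clusters.hubs[i] for i in clusters.significant),
            }

        if stages.get("enrich"):
            annotations = iotables.read_table(paths["annotations"], "annotations")
            report = enrich.enrich_query(
                seeds,
                annotations,
                method=params["enrich_method"],
                alpha=float(params["enrich_alpha"]),
                kappa_min=float(params["kappa_min"]),
                linkage_fraction=float(params["linkage_fraction"]),
            )
            emit("enrichment_terms.tsv", report)
            emit("enrichment_clusters.tsv", report.cluster_frame())
            run_log["stages"]["enrich"] = {
                "n_terms": int(len(report.terms)),
                "n_clusters": len(report.clusters),
                "n_significant_clusters": sum(c.significant for c in report.clusters),
            }

        if stages.get("biomarker"):
            csf = iotables.read_id_list(paths["csf_list"])
            plasma = iotables.read_id_list(paths["plasma_list"])
            venn = biomarker.overlap3(seeds, csf, plasma)
            emit("biomarker_venn.tsv", venn)
            run_log["stages"]["biomarker"] = {
                "counts": venn.counts,
                "triple_members": venn.triple_members,
            }

        complete = True
        return run_log
    finally:
        (out / "run_log.json").write_text(
            json.dumps(run_log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest_lines = [f"complete: {str(complete).lower()}"] + sorted(manifest)
        (out / "MANIFEST").write_text("\n".join(manifest_lines) + "\n", encoding="utf-8")


def _run_convergence(paths, params, run_log, emit):
    """Stages prefilter + converge; returns the result and per-region tables."""
    metadata = iotables.read_table(paths["gene_metadata"], "gene_metadata")
    eligible_df, flog = prefilter.filter_gene_types(metadata)
    eligible = set(eligible_df["symbol"])
    run_log["stages"]["gene_filter"] = {
        "n_input": int(len(metadata)),
        "n_kept": len(eligible),
        "removed": flog.counts,
    }
    logger.info("gene-type filter: %d -> %d", len(metadata), len(eligible))

    # GWL: linkage-region gene selection, then score join
    regions = iotables.read_table(paths["linkage_regions"], "linkage_regions")
    coords = iotables.read_table(paths["gene_coords"], "gene_coords")
    selected = prefilter.select_linkage_genes(
        regions, coords, lod_min=float(params["lod_min"]),
        p_max=float(params["region_p_max"])
    )
    gwl_scores = iotables.read_table(paths["gwl_scores"], "gene_scores")
    gwl_table = gwl_scores[
        gwl_scores["symbol"].isin(selected & eligible)
    ].reset_index(drop=True)
    gwl = rankaggr.rank_genes(gwl_table, "higher_better", "GWL")
    run_log["stages"]["gwl"] = {
        "n_regions": int(len(regions)),
        "n_region_genes": len(selected),
        "n_ranked": len(gwl),
        "symbols": sorted(gwl_table["symbol"]),
    }

    # GWA: SNP filter and per-gene minimum weighted p
    snps = iotables.read_table(paths["snp_assoc"], "snp_assoc")
    gwa_table = prefilter.select_association_genes(snps, p_max=float(params["gwa_p_max"]))
    gwa_table = gwa_table[gwa_table["symbol"].isin(eligible)].reset_index(drop=True)
    gwa = rankaggr.rank_genes(gwa_table, "lower_better", "GWA")
    run_log["stages"]["gwa"] = {
        "n_snps": int(len(snps)),
        "n_ranked": len(gwa),
        "symbols": sorted(gwa_table["symbol"]),
    }

    # GWE: per-region collapse + filter, then six-region merge
    probes = iotables.read_table(
        paths["expression_probes"], "expression_probes",
        log2_fold_change=bool(params["log2_fold_change"]),
    )
    per_region_filtered = {}
    for region, table in probes.groupby("region", sort=True):
        collapsed = prefilter.collapse_probes(table)
        per_region_filtered[region] = prefilter.filter_expression(
            collapsed,
            adjp_max=float(params["adjp_max"]),
            fc_up=float(params["fc_up"]),
            fc_down=float(params["fc_down"]),
        )
    merged = prefilter.merge_regions(per_region_filtered)
    gwe_table = merged[merged["symbol"].isin(eligible)].reset_index(drop=True)
    gwe = rankaggr.rank_genes(gwe_table[["symbol", "score"]], "lower_better", "GWE")
    run_log["stages"]["gwe"] = {
        "n_probes": int(len(probes)),
        "n_regions": len(per_region_filtered),
        "n_merged": int(len(merged)),
        "n_ranked": len(gwe),
    }

    conv = rankaggr.converge(gwl, gwa, gwe)
    emit("convergence.tsv", conv)
    run_log["stages"]["convergence"] = {
        "modality_sizes": conv.modality_sizes,
        "n_genes": len(conv),
    }
    logger.info(
        "convergence: %s -> %d genes", conv.modality_sizes, len(conv)
    )
    return conv, per_region_filtered
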