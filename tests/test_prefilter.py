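"""Dataset-specific selection rules and their brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from convergene import prefilter


def gene_row(symbol, locus_type="protein_coding", band="1q21.1", status="active"):
    return {
        "symbol": symbol,
        "hgnc_id": "",
        "locus_type": locus_type,
        "chromosome_band": band,
        "status": status,
    }


class TestFilterGeneTypes:
    def test_excluded_classes_removed(self):
        genes = pd.DataFrame(
            [
                gene_row("A"),
                gene_row("B", locus_type="pseudogene"),
                gene_row("C", locus_type="microRNA"),
            ]
        )
        kept, log = prefilter.filter_gene_types(genes)
        assert list(kept["symbol"]) == ["A"]
        assert log.counts == {"locus_type:microRNA": 1, "locus_type:pseudogene": 1}

    def test_all_protein_coding_is_noop(self):
        genes = pd.DataFrame([gene_row(s) for s in "ABC"])
        kept, log = prefilter.filter_gene_types(genes)
        assert list(kept["symbol"]) == list(genes["symbol"])
        assert log.total_removed == 0

    def test_chromosome_x_bands_removed(self):
        genes = pd.DataFrame(
            [gene_row("A"), gene_row("B", band="Xp21.1"), gene_row("C", band="Xq28")]
        )
        kept, log = prefilter.filter_gene_types(genes)
        assert list(kept["symbol"]) == ["A"]
        assert log.counts == {"band:^Xp": 1, "band:^Xq": 1}

    def test_unknown_locus_type_is_error(self):
        genes = pd.DataFrame([gene_row("A", locus_type="mystery")])
        with pytest.raises(ValueError, match="mystery"):
            prefilter.filter_gene_types(genes)

    def test_removal_log_matches_planted_counts(self):
        rng = np.random.default_rng(11)
        classes = ["protein_coding", "pseudogene", "ncRNA", "orf", "hypothetical"]
        draws = rng.choice(len(classes), size=200)
        genes = pd.DataFrame(
            [gene_row(f"G{i:03d}", locus_type=classes[d]) for i, d in enumerate(draws)]
        )
        planted = {
            f"locus_type:{c}": int((draws == i).sum())
            for i, c in enumerate(classes)
            if c != "protein_coding" and (draws == i).sum()
        }
        kept, log = prefilter.filter_gene_types(genes)
        assert log.counts == planted
        assert len(kept) == int((draws == 0).sum())


class TestSelectLinkageGenes:
    def region(self, chrom, start, end, lod=None, p=None):
        return {"chromosome": chrom, "start_bp": start, "end_bp": end,
                "lod": lod, "p_value": p}

    def gene(self, sym, chrom, start, end):
        return {"chromosome": chrom, "start_bp": start, "end_bp": end, "symbol": sym}

    def test_lod_threshold_is_inclusive(self):
        regions = pd.DataFrame([self.region("1", 0, 1000, lod=2.0),
                                self.region("2", 0, 1000, lod=1.99)])
        genes = pd.DataFrame([self.gene("A", "1", 10, 20), self.gene("B", "2", 10, 20)])
        assert prefilter.select_linkage_genes(regions, genes) == {"A"}

    def test_halfopen_abutment_is_not_overlap(self):
        regions = pd.DataFrame([self.region("1", 200, 300, lod=3.0)])
        genes = pd.DataFrame([self.gene("A", "1", 100, 200)])
        assert prefilter.select_linkage_genes(regions, genes) == set()

    def test_region_without_lod_or_p_is_error(self):
        regions = pd.DataFrame([self.region("1", 0, 100)])
        genes = pd.DataFrame([self.gene("A", "1", 10, 20)])
        with pytest.raises(ValueError):
            prefilter.select_linkage_genes(regions, genes)

    def test_matches_bruteforce_allpairs_scan(self):
        rng = np.random.default_rng(5)
        regions = pd.DataFrame(
            [
                self.region(
                    str(rng.integers(1, 4)),
                    int(s := rng.integers(0, 10_000)),
                    int(s + rng.integers(1, 3_000)),
                    lod=float(rng.uniform(0, 4)),
                    p=float(rng.uniform(0.001, 0.5)),
                )
                for _ in range(5)
            ]
        )
        genes = pd.DataFrame(
            [
                self.gene(
                    f"G{i}",
                    str(rng.integers(1, 4)),
                    int(s := rng.integers(0, 12_000)),
                    int(s + rng.integers(1, 500)),
                )
                for i in range(50)
            ]
        )
        expected = set()
        for _, g in genes.iterrows():
            for _, r in regions.iterrows():
                if (r["lod"] >= 2.0 or r["p_value"] < 0.05) and str(
                    g["chromosome"]
                ) == str(r["chromosome"]):
                    if g["start_bp"] < r["end_bp"] and r["start_bp"] < g["end_bp"]:
                        expected.add(g["symbol"])
        assert prefilter.select_linkage_genes(regions, genes) == expected

    def test_relaxing_lod_never_shrinks_selection(self):
        rng = np.random.default_rng(8)
        regions = pd.DataFrame(
            [self.region("1", int(i * 1000), int(i * 1000 + 900),
                         lod=float(rng.uniform(0, 4))) for i in range(10)]
        )
        genes = pd.DataFrame(
            [self.gene(f"G{i}", "1", int(rng.integers(0, 10_000)),
                       int(rng.integers(0, 10_000)) + 100) for i in range(40)]
        )
        strict = prefilter.select_linkage_genes(regions, genes, lod_min=3.0)
        loose = prefilter.select_linkage_genes(regions, genes, lod_min=1.0)
        assert strict <= loose


class TestSelectAssociationGenes:
    def test_min_per_gene_and_unmapped_dropped(self):
        snps = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3"],
                "symbol": ["G1", "G1", ""],
                "weighted_p": [5e-4, 2e-4, 1e-5],
            }
        )
        out = prefilter.select_association_genes(snps)
        assert dict(zip(out["symbol"], out["score"])) == {"G1": 2e-4}

    def test_threshold_is_strict(self):
        snps = pd.DataFrame(
            {"snp_id": ["rs1", "rs2"], "symbol": ["G1", "G2"], "weighted_p": [1e-3, 1e-3]}
        )
        assert prefilter.select_association_genes(snps, p_max=1e-3).empty

    def test_matches_groupby_minimum_oracle(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i:03d}" for i in range(100)]
        snps = pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(1000)],
                "symbol": rng.choice(genes, size=1000),
                "weighted_p": rng.uniform(0, 2e-3, size=1000),
            }
        )
        out = prefilter.select_association_genes(snps)
        expected = {}
        for _, row in snps.iterrows():
            if row["weighted_p"] < 1e-3:
                g = row["symbol"]
                expected[g] = min(expected.get(g, 1.0), row["weighted_p"])
        assert dict(zip(out["symbol"], out["score"])) == pytest.approx(expected)


def probe(symbol, fc, var, probe_id="p", adjp=0.01, region="EC"):
    return {
        "probe_id": probe_id,
        "symbol": symbol,
        "fold_change": fc,
        "adjusted_p": adjp,
        "variance": var,
        "region": region,
    }


class TestCollapseProbes:
    def test_highest_variance_probe_wins_when_concordant(self):
        probes = pd.DataFrame(
            [probe("G", 2.2, 1.0, "p1"), probe("G", 3.0, 0.5, "p2")]
        )
        out = prefilter.collapse_probes(probes)
        assert len(out) == 1
        assert out.iloc[0]["fold_change"] == 2.2

    def test_discordant_gene_removed_entirely(self):
        probes = pd.DataFrame([probe("G", 2.2, 1.0, "p1"), probe("G", 0.4, 0.5, "p2")])
        assert prefilter.collapse_probes(probes).empty

    def test_fc_exactly_one_mixed_with_direction_is_discordant(self):
        probes = pd.DataFrame([probe("G", 1.0, 1.0, "p1"), probe("G", 2.5, 0.5, "p2")])
        assert prefilter.collapse_probes(probes).empty

    def test_all_probes_exactly_one_is_kept(self):
        probes = pd.DataFrame([probe("G", 1.0, 1.0, "p1"), probe("G", 1.0, 0.5, "p2")])
        out = prefilter.collapse_probes(probes)
        assert list(out["symbol"]) == ["G"]

    def test_mixed_regions_rejected(self):
        probes = pd.DataFrame([probe("G", 2.0, 1.0, region="EC"),
                               probe("H", 2.0, 1.0, region="HIP")])
        with pytest.raises(ValueError, match="single region"):
            prefilter.collapse_probes(probes)

    def test_planted_concordance_fixture_resolved_exactly(self):
        rng = np.random.default_rng(21)
        rows, expected = [], {}
        pid = iter(range(10_000))
        for i in range(50):
            sym = f"G{i:02d}"
            m = int(rng.integers(1, 5))
            discordant = m > 1 and rng.random() < 0.4
            direction = 1 if rng.random() < 0.5 else -1
            variances = rng.uniform(0.1, 5.0, size=m)
            for j in range(m):
                d = -direction if (discordant and j == 0) else direction
                fc = float(1 + rng.uniform(0.1, 3.0)) if d > 0 else float(rng.uniform(0.1, 0.9))
                rows.append(probe(sym, fc, float(variances[j]), f"p{next(pid)}"))
            if not discordant:
                expected[sym] = float(variances.max())
        out = prefilter.collapse_probes(pd.DataFrame(rows))
        assert dict(zip(out["symbol"], out["variance"])) == pytest.approx(expected)
        assert out["symbol"].is_unique


class TestFilterExpression:
    @pytest.mark.parametrize(
        "fc,adjp,kept",
        [
            (2.0, 0.049, True),   # FC boundary inclusive
            (1.9, 0.001, False),  # inside the FC dead zone
            (0.5, 0.05, False),   # adjusted-p cut is strict
            (0.5, 0.049, True),
            (0.45, 0.01, True),
        ],
    )
    def test_threshold_boundaries(self, fc, adjp, kept):
        rows = pd.DataFrame([probe("G", fc, 1.0, adjp=adjp)])
        out = prefilter.filter_expression(rows)
        assert (len(out) == 1) is kept

    def test_matches_direct_predicate_on_random_table(self):
        rng = np.random.default_rng(17)
        rows = pd.DataFrame(
            [
                probe(f"G{i}", float(rng.uniform(0.1, 4.0)), 1.0,
                      adjp=float(rng.uniform(0, 0.2)))
                for i in range(500)
            ]
        )
        out = set(prefilter.filter_expression(rows)["symbol"])
        expected = {
            r["symbol"]
            for _, r in rows.iterrows()
            if r["adjusted_p"] < 0.05 and (r["fold_change"] >= 2.0 or r["fold_change"] <= 0.5)
        }
        assert out == expected


class TestMergeRegions:
    def test_minimum_adjusted_p_and_region_set(self):
        ec = pd.DataFrame([probe("G", 2.5, 1.0, adjp=0.01, region="EC")])
        hip = pd.DataFrame([probe("G", 2.5, 1.0, adjp=0.002, region="HIP")])
        out = prefilter.merge_regions({"EC": ec, "HIP": hip})
        assert len(out) == 1
        assert out.iloc[0]["score"] == 0.002
        assert out.iloc[0]["regions"] == "EC,HIP"

    def test_single_region_is_identity_up_to_schema(self):
        ec = pd.DataFrame([probe("A", 2.5, 1.0, adjp=0.01), probe("B", 0.4, 1.0, adjp=0.03)])
        out = prefilter.merge_regions({"EC": ec})
        assert dict(zip(out["symbol"], out["score"])) == {"A": 0.01, "B": 0.03}

    def test_empty_region_map_is_error(self):
        with pytest.raises(ValueError):
            prefilter.merge_regions({})

    def test_union_and_minima_match_bruteforce(self):
        rng = np.random.default_rng(23)
        regions = {}
        expected: dict = {}
        for r in ("EC", "HIP", "MTG", "PC", "SFG", "VCX"):
            members = rng.choice([f"G{i:02d}" for i in range(40)], size=15, replace=False)
            rows = [
                probe(m, 2.5, 1.0, adjp=float(rng.uniform(0, 0.05)), region=r)
                for m in members
            ]
            regions[r] = pd.DataFrame(rows)
            for row in rows:
                expected[row["symbol"]] = min(
                    expected.get(row["symbol"], 1.0), row["adjusted_p"]
                )
        out = prefilter.merge_regions(regions)
        assert dict(zip(out["symbol"], out["score"])) == pytest.approx(expected)


class TestRegionSpecificOverlap:
    def test_triple_intersections_computed_per_region(self):
        per_region = {"EC": {"A", "B"}, "HIP": {"C"}}
        out = prefilter.region_specific_overlap(per_region, {"A", "C"}, {"A", "B", "C"})
        assert out == {"EC": {"A"}, "HIP": {"C"}}

    def test_subset_region_returns_itself(self):
        per_region = {"EC": {"A", "B"}}
        out = prefilter.region_specific_overlap(
            per_region, {"A", "B", "C"}, {"A", "B", "D"}
        )
        assert out["EC"] == {"A", "B"}
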