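from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest
import yaml

from convergene import synthgen


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """Default synthetic study (seed 7), written once per session."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = synthgen.SynthConfig(seed=7)
    bundle, truth = synthgen.generate_study(cfg, out)
    return {"config": cfg, "bundle": bundle, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def pipeline_config(study_bundle, tmp_path_factory):
    """YAML config pointing at the session bundle."""
    d = study_bundle["dir"]
    conf = {
        "inputs": {
            "gene_metadata": str(d / "gene_metadata.tsv"),
            "gene_coords": str(d / "gene_coords.tsv"),
            "linkage_regions": str(d / "linkage_regions.tsv"),
            "gwl_scores": str(d / "gwl_scores.tsv"),
            "snp_assoc": str(d / "snp_assoc.tsv"),
            "expression_probes": str(d / "expression_probes.tsv"),
            "edges": str(d / "edges.tsv"),
            "localization": str(d / "localization.tsv"),
            "annotations": str(d / "annotations.tsv"),
            "csf_list": str(d / "csf.txt"),
            "plasma_list": str(d / "plasma.txt"),
        }
    }
    path = tmp_path_factory.mktemp("config") / "config.yaml"
    path.write_text(yaml.safe_dump(conf), encoding="utf-8")
    return path


def write_tsv(path: Path, header: list, rows: list) -> Path:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def make_tsv(tmp_path):
    def _make(name, header, rows):
        return write_tsv(tmp_path / name, header, rows)

    return _make
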