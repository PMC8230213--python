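"""End-to-end pipeline: classify -> profile -> associate -> SKAT-O, with a
manifest for reproducibility and a co-mutation graph export.

The graph export is a structural stand-in for proprietary network
analysis: nodes are genes, edges connect pairs whose co-occurrence
correlation is significant at a threshold, with r and p as attributes.
It makes no biological claims.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as vio
from .association import association_screen, pearson_binary_correlation, variant_maf_hwe_table
from .filtration import FilterConfig, cascade_counts, classify
from .profiling import (CRITERIA, cohort_summary, gene_sample_matrix, gene_summary,
                        select_recurrent_genes, stratify)
from .skat import skat_o_screen

logger = logging.getLogger("oncopanel")

DEFAULT_AXES = ("stage_group", "site", "gender", "age_group", "lymph_node", "metastasis")
SKAT_AXES = ("stage_group", "gender", "age_group", "site")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; round-trips losslessly through YAML."""

    vcf_dir: str | None = None
    calls_tsv: str | None = None
    annotations_tsv: str = "annotations.tsv"
    patients_tsv: str = "patients.tsv"
    out_dir: str = "results"
    filter: FilterConfig = field(default_factory=FilterConfig)
    axes: tuple[str, ...] = DEFAULT_AXES
    skat_axes: tuple[str, ...] = SKAT_AXES
    skat_weights_beta: tuple[float, float] = (1.0, 25.0)
    skat_rho_grid: tuple[float, ...] = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)
    skat_n_permutations: int = 0
    n_tests: int = 409
    min_recurrent_patients: int = 3
    comutation_p_threshold: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter"] = dataclasses.asdict(self.filter)
        d["filter"]["germline_vaf_bands"] = [list(b) for b in self.filter.germline_vaf_bands]
        for key in ("axes", "skat_axes", "skat_weights_beta", "skat_rho_grid"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        fc = data.pop("filter", {})
        fc["germline_vaf_bands"] = tuple(tuple(b) for b in fc.get("germline_vaf_bands", ()))
        data["filter"] = FilterConfig(**fc)
        for key in ("axes", "skat_axes", "skat_weights_beta", "skat_rho_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def export_comutation_graph(correlation, p_threshold: float = 0.05) -> nx.Graph:
    """Gene co-mutation graph: an edge per pair with p below the threshold."""
    graph = nx.Graph()
    graph.add_nodes_from(correlation.genes)
    genes = correlation.genes
    for i, gi in enumerate(genes):
        for gj in genes[i + 1:]:
            p = float(correlation.p.loc[gi, gj])
            if np.isfinite(p) and p < p_threshold:
                graph.add_edge(gi, gj, r=float(correlation.r.loc[gi, gj]), p=p)
    return graph


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to out_dir).

    Identical config and inputs yield byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        vio.write_tsv(path, df)
        artifacts[name] = str(path)

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.calls_tsv:
            calls = vio.read_calls_tsv(config.calls_tsv)
        elif config.vcf_dir:
            calls = vio.read_vcf_dir(config.vcf_dir)
        else:
            raise ValueError("config must set calls_tsv or vcf_dir")
        annotations = vio.read_annotations(config.annotations_tsv)
        logger.info("inputs: %d calls, %d annotation rows", len(calls), len(annotations))
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "classification"
    try:
        classified = classify(calls, annotations, config.filter)
        counts = cascade_counts(classified)
        _write("classified.tsv", classified)
        (out_dir / "cascade_counts.json").write_text(
            json.dumps(counts.to_dict(), indent=2, sort_keys=True))
        artifacts["cascade_counts.json"] = str(out_dir / "cascade_counts.json")
        logger.info("classification: %d variants (%d passed quality, %d novel-vs-both)",
                    counts.n_total_all, counts.n_total, counts.n_novel_vs_both)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "profiling"
    try:
        patients = vio.read_patients(config.patients_tsv)
        matrices = {c: gene_sample_matrix(classified, calls, c) for c in CRITERIA}
        for crit, matrix in matrices.items():
            _write(f"matrix_{crit}.tsv", matrix.reset_index())
        summary = gene_summary(classified, matrices["any"], matrices["somatic"],
                               matrices["pathogenic"], matrices["tissue_specific_pathogenic"])
        _write("gene_summary.tsv", summary)
        _write("cohort_summary.tsv", cohort_summary(patients))
        recurrent = select_recurrent_genes(matrices["tissue_specific_pathogenic"],
                                           config.min_recurrent_patients)
        for axis in config.axes:
            strata = stratify(matrices["tissue_specific_pathogenic"].loc[recurrent],
                              patients, axis)
            _write(f"strata_{axis}.tsv", strata.reset_index())
        logger.info("profiling: %d recurrent genes (>=%d patients)",
                    len(recurrent), config.min_recurrent_patients)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "association"
    try:
        recurrent_matrix = matrices["tissue_specific_pathogenic"].loc[recurrent]
        assoc = association_screen(recurrent_matrix, patients, tuple(config.axes[:4]))
        _write("association.tsv", assoc)
        _write("maf_hwe.tsv", variant_maf_hwe_table(classified, calls))
        if len(recurrent) >= 2 and recurrent_matrix.shape[1] >= 3:
            corr = pearson_binary_correlation(recurrent_matrix)
            _write("correlation_r.tsv", corr.r.reset_index(names="gene"))
            _write("correlation_p.tsv", corr.p.reset_index(names="gene"))
            _write("correlation_stars.tsv", corr.stars().reset_index(names="gene"))
            graph = export_comutation_graph(corr, config.comutation_p_threshold)
            graph_path = out_dir / "comutation.graphml"
            nx.write_graphml(graph, graph_path)
            artifacts["comutation.graphml"] = str(graph_path)
            logger.info("association: %d co-mutation edges at p < %g",
                        graph.number_of_edges(), config.comutation_p_threshold)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "skat"
    try:
        for axis in config.skat_axes:
            result = skat_o_screen(
                classified, calls, patients, axis,
                weights_beta=config.skat_weights_beta, rho_grid=config.skat_rho_grid,
                n_tests=config.n_tests, n_permutations=config.skat_n_permutations,
                seed=config.seed)
            _write(f"skat_{axis}.tsv", result)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {"oncopanel": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "artifacts": sorted(artifacts),
        "paths": {k: artifacts[k] for k in sorted(artifacts)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
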