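"""End-to-end pipeline: enrichment -> layers -> network -> clustering ->
candidates -> (optional) robustness and indication distances, with a
reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster import clusterone, louvain, mixed_clusters, write_cluster_meta, write_clusters
from .corpus import CATEGORIES, enrichment_universe, load_corpus, load_gmt, load_ppi
from .enrich import feature_attribute_map, profile_corpus, write_profiles
from .network import (
    GENE_LAYER,
    assemble_network,
    build_layer,
    network_summary,
    write_edges,
    write_graphml,
    write_nodes,
)
from .reposition import (
    candidates_both,
    consensus,
    indication_distances,
    robustness,
    write_candidates,
    write_distances,
    write_robustness,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run; round-trips via YAML."""

    disease_genes: str = ""
    drug_targets: str = ""
    indications: str = ""
    biological_process: str = ""
    pathway: str = ""
    phenotype: str = ""
    ppi: str | None = None
    secondary_targets: str | None = None
    drug_id_map: str | None = None
    out_dir: str = "out"

    alpha: float = 0.05
    jaccard_cutoff: float = 0.5
    penalty_per_node: float = 2.0
    min_size: int = 3
    min_density: float = 0.3
    overlap_merge_threshold: float = 0.8
    cluster_alpha: float = 0.05
    robustness_fraction: float = 0.1
    robustness_reps: int = 10
    run_robustness: bool = False
    run_distances: bool = False
    graphml: bool = False
    strict: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.jaccard_cutoff <= 1.0:
            raise ValueError(f"jaccard_cutoff must be in [0, 1], got {self.jaccard_cutoff}")
        if not 0.0 < self.alpha <= 1.0 or not 0.0 < self.cluster_alpha <= 1.0:
            raise ValueError("significance levels must be in (0, 1]")
        if not 0.0 < self.robustness_fraction < 1.0:
            raise ValueError("robustness_fraction must be in (0, 1)")
        if self.robustness_reps < 1 or self.min_size < 1:
            raise ValueError("robustness_reps and min_size must be >= 1")
        if self.penalty_per_node < 0:
            raise ValueError("penalty_per_node must be non-negative")
        for key in ("disease_genes", "drug_targets", "indications", *CATEGORIES):
            if not getattr(self, key):
                raise ValueError(f"config is missing required input path: {key}")

    @property
    def clusterone_params(self) -> dict:
        return {
            "penalty_per_node": self.penalty_per_node,
            "min_size": self.min_size,
            "min_density": self.min_density,
            "overlap_merge_threshold": self.overlap_merge_threshold,
            "alpha": self.cluster_alpha,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write all artifacts under
    ``config.out_dir``; returns the run manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
    }

    corpus = load_corpus(
        config.disease_genes,
        config.drug_targets,
        config.indications,
        config.secondary_targets,
        config.drug_id_map,
        strict=config.strict,
    )
    for key in ("disease_genes", "drug_targets", "indications", *CATEGORIES, "ppi"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
    manifest["stages"]["load"] = {
        "n_diseases": len(corpus.diseases),
        "n_drugs": len(corpus.drugs),
        "n_known_indications": len(corpus.known_indications),
    }

    libraries = [load_gmt(getattr(config, cat), cat, strict=config.strict) for cat in CATEGORIES]
    universe = enrichment_universe(corpus, libraries)
    profiles = profile_corpus(corpus, libraries, alpha=config.alpha, universe=universe)
    write_profiles(out / "enrichment.tsv", profiles)
    manifest["stages"]["enrich"] = {
        "universe_size": len(universe),
        "n_profiled": len(profiles),
    }

    attr_maps = {GENE_LAYER: {**corpus.diseases, **corpus.drugs}}
    for cat in CATEGORIES:
        attr_maps[cat] = feature_attribute_map(profiles, cat)
    layers = [build_layer(attr_maps[lab], lab, config.jaccard_cutoff) for lab in attr_maps]
    net = assemble_network(layers, corpus.node_types)
    write_edges(out / "edges.tsv", net)
    write_nodes(out / "nodes.tsv", net)
    if config.graphml:
        write_graphml(out / "network.graphml", net)
    summary = network_summary(net)
    manifest["stages"]["network"] = dataclasses.asdict(summary)
    manifest["stages"]["layers"] = {lay.label: len(lay.edges) for lay in layers}

    types = net.node_types
    part = louvain(net, seed=config.seed)
    louvain_cs = part.to_cluster_set()
    c1_cs = clusterone(net, seed=config.seed, **config.clusterone_params)
    for cs in (louvain_cs, c1_cs):
        write_clusters(out / f"clusters_{cs.algorithm}.tsv", cs, types)
        write_cluster_meta(out / f"cluster_meta_{cs.algorithm}.tsv", cs)
    manifest["stages"]["clustering"] = {
        "louvain_modules": len(louvain_cs),
        "louvain_mixed": len(mixed_clusters(louvain_cs, types)),
        "louvain_q": part.q,
        "clusterone_modules": len(c1_cs),
        "clusterone_mixed": len(mixed_clusters(c1_cs, types)),
    }

    cands = candidates_both(
        net, corpus.known_indications, seed=config.seed, clusterone_params=config.clusterone_params
    )
    cons = consensus(cands["louvain"], cands["clusterone"])
    write_candidates(out / "candidates_louvain.tsv", cands["louvain"], corpus.names)
    write_candidates(out / "candidates_clusterone.tsv", cands["clusterone"], corpus.names)
    write_candidates(out / "candidates_consensus.tsv", cons, corpus.names)
    manifest["stages"]["candidates"] = {
        "louvain": len(cands["louvain"].pairs),
        "clusterone": len(cands["clusterone"].pairs),
        "consensus": len(cons.pairs),
        "known_recovered": len(cons.known_recovered),
    }

    if config.run_robustness:
        report = robustness(
            net,
            corpus.known_indications,
            fraction=config.robustness_fraction,
            reps=config.robustness_reps,
            master_seed=config.seed,
            clusterone_params=config.clusterone_params,
        )
        write_robustness(out / "robustness", report)
        manifest["stages"]["robustness"] = json.loads(report.to_json())

    if config.run_distances:
        if not config.ppi:
            raise ValueError("run_distances requires a ppi input path")
        ppi = load_ppi(config.ppi, strict=config.strict)
        report = indication_distances(ppi, corpus.known_indications, corpus.diseases, corpus.drugs)
        write_distances(out / "distances", report)
        manifest["stages"]["distances"] = json.loads(report.to_json())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    log.info("pipeline complete; artifacts in %s", out)
    return manifest
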