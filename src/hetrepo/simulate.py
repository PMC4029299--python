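"""Synthetic annotation corpora with planted disease-drug module structure.

Each planted module owns a private gene pool; its member diseases and drugs
draw most of their genes from that pool (so within-module gene Jaccard
clears the 0.5 network cutoff by construction) with an optional
contamination probability of swapping a gene for one from another module's
pool.  Feature libraries are generated aligned to the pools — one feature
per module and category plus decoy features over the background pool — so
the enrichment-based layers genuinely link module members beyond shared
genes.  Background entities draw from a large shared pool and stay
unconnected at the default cutoff.  Known indications are sampled from
within-module disease-drug pairs; the remaining within-module pairs form
the ground-truth expected candidate set.  Everything is a pure, seeded
function of the design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .corpus import (
    CATEGORIES,
    AnnotationCorpus,
    FeatureLibrary,
    PpiGraph,
    build_corpus,
    write_associations,
    write_gmt,
    write_indications,
    write_ppi,
)

Pair = tuple[str, str]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted-module generator.

    Defaults give 10 modules of 3 diseases + 10 drugs over 10-gene pools
    with 8 genes per entity (within-module Jaccard floor 0.6 at zero
    contamination), light contamination, and a small unstructured
    background — a corpus the full pipeline processes in seconds.
    """

    n_modules: int = 10
    diseases_per_module: int = 3
    drugs_per_module: int = 10
    genes_per_module_pool: int = 10
    genes_per_entity: int = 8
    background_diseases: int = 5
    background_drugs: int = 10
    background_gene_pool: int = 200
    contamination: float = 0.05
    features_per_category_per_module: int = 1
    decoy_features_per_category: int = 5
    indication_rate: float = 0.1
    ppi_intermodule_edges: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_modules,
            self.diseases_per_module,
            self.drugs_per_module,
            self.genes_per_module_pool,
            self.genes_per_entity,
            self.features_per_category_per_module,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all module/entity/gene counts must be positive")
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination probability must be in [0, 1)")
        if not 0.0 <= self.indication_rate <= 1.0:
            raise ValueError("indication rate must be in [0, 1]")
        if self.genes_per_entity > self.genes_per_module_pool:
            raise ValueError(
                "genes_per_entity exceeds the module pool size: infeasible design"
            )

    def with_seed(self, seed: int) -> "PlantedDesign":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """Planted memberships and the expected candidate output."""

    module_diseases: tuple[tuple[str, ...], ...]
    module_drugs: tuple[tuple[str, ...], ...]
    module_pools: tuple[frozenset[str], ...]
    known_indications: frozenset[Pair]
    expected_candidates: frozenset[Pair]

    def __post_init__(self) -> None:
        if self.expected_candidates & self.known_indications:
            raise ValueError("expected candidates overlap sampled known indications")


def _entity_genes(rng: np.random.Generator, pool: list[str], other: list[str], design: PlantedDesign) -> frozenset[str]:
    genes = list(rng.choice(pool, size=design.genes_per_entity, replace=False))
    if design.contamination > 0 and other:
        swap = rng.random(len(genes)) < design.contamination
        for i in np.flatnonzero(swap):
            genes[i] = str(rng.choice(other))
    return frozenset(genes)


def generate(design: PlantedDesign) -> tuple[AnnotationCorpus, list[FeatureLibrary], GroundTruth]:
    """Generate a corpus, its three feature libraries, and the ground truth."""
    rng = np.random.default_rng(design.seed)
    pools = [
        [f"G{m:02d}_{i:02d}" for i in range(design.genes_per_module_pool)]
        for m in range(design.n_modules)
    ]
    bg_pool = [f"BG{i:03d}" for i in range(design.background_gene_pool)]

    diseases: dict[str, frozenset[str]] = {}
    drugs: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    mod_dis: list[tuple[str, ...]] = []
    mod_dru: list[tuple[str, ...]] = []
    for m in range(design.n_modules):
        other = [g for mm, p in enumerate(pools) if mm != m for g in p]
        ds, rs = [], []
        for i in range(design.diseases_per_module):
            did = f"D{m:02d}_{i:02d}"
            diseases[did] = _entity_genes(rng, pools[m], other, design)
            names[did] = f"disease {m}.{i}"
            ds.append(did)
        for j in range(design.drugs_per_module):
            rid = f"R{m:02d}_{j:02d}"
            drugs[rid] = _entity_genes(rng, pools[m], other, design)
            names[rid] = f"drug {m}.{j}"
            rs.append(rid)
        mod_dis.append(tuple(ds))
        mod_dru.append(tuple(rs))
    for i in range(design.background_diseases):
        did = f"DB{i:02d}"
        diseases[did] = frozenset(rng.choice(bg_pool, size=design.genes_per_entity, replace=False))
        names[did] = f"background disease {i}"
    for j in range(design.background_drugs):
        rid = f"RB{j:02d}"
        drugs[rid] = frozenset(rng.choice(bg_pool, size=design.genes_per_entity, replace=False))
        names[rid] = f"background drug {j}"

    libraries = []
    for category in CATEGORIES:
        sets: dict[str, frozenset[str]] = {}
        fnames: dict[str, str] = {}
        for m in range(design.n_modules):
            for k in range(design.features_per_category_per_module):
                fid = f"{category[:2].upper()}_M{m:02d}_{k}"
                if k == 0:
                    genes = frozenset(pools[m])
                else:
                    size = max(2, int(0.7 * design.genes_per_module_pool))
                    genes = frozenset(rng.choice(pools[m], size=size, replace=False))
                sets[fid] = genes
                fnames[fid] = f"{category} feature {k} of module {m}"
        for k in range(design.decoy_features_per_category):
            fid = f"{category[:2].upper()}_DECOY_{k}"
            size = design.genes_per_entity + 2
            sets[fid] = frozenset(rng.choice(bg_pool, size=size, replace=False))
            fnames[fid] = f"{category} decoy feature {k}"
        libraries.append(FeatureLibrary(category=category, sets=sets, names=fnames))

    known: set[Pair] = set()
    expected: set[Pair] = set()
    for m in range(design.n_modules):
        for d in mod_dis[m]:
            for r in mod_dru[m]:
                if rng.random() < design.indication_rate:
                    known.add((d, r))
                else:
                    expected.add((d, r))

    corpus = build_corpus(diseases, drugs, names, known)
    truth = GroundTruth(
        module_diseases=tuple(mod_dis),
        module_drugs=tuple(mod_dru),
        module_pools=tuple(frozenset(p) for p in pools),
        known_indications=frozenset(known),
        expected_candidates=frozenset(expected),
    )
    return corpus, libraries, truth


def generate_ppi(corpus: AnnotationCorpus, design: PlantedDesign) -> PpiGraph:
    """A protein-interaction fixture aligned with the planted modules.

    Each module pool is wired as a clique (within-module gene pairs at
    distance 1), modules are bridged by a few random inter-module edges,
    and background genes used by any entity are chained so they stay
    reachable from each other but far from the modules.
    """
    rng = np.random.default_rng([design.seed, 1])
    pools = [
        [f"G{m:02d}_{i:02d}" for i in range(design.genes_per_module_pool)]
        for m in range(design.n_modules)
    ]
    edges: set[frozenset[str]] = set()
    for pool in pools:
        for i, a in enumerate(pool):
            for b in pool[i + 1 :]:
                edges.add(frozenset((a, b)))
    if design.n_modules > 1:
        for _ in range(design.ppi_intermodule_edges):
            ma, mb = rng.choice(design.n_modules, size=2, replace=False)
            a = str(rng.choice(pools[ma]))
            b = str(rng.choice(pools[mb]))
            edges.add(frozenset((a, b)))
    bg_used = sorted(
        g
        for genes in list(corpus.diseases.values()) + list(corpus.drugs.values())
        for g in genes
        if g.startswith("BG")
    )
    for a, b in zip(bg_used, bg_used[1:]):
        if a != b:
            edges.add(frozenset((a, b)))
    nodes = frozenset().union(*edges) if edges else frozenset()
    return PpiGraph(edges=frozenset(edges), nodes=nodes)


def write_bundle(out_dir: str | Path, design: PlantedDesign) -> dict[str, Path]:
    """Write a complete synthetic input bundle in the dialects the loaders
    read, plus the ground truth as JSON; returns the file map."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus, libraries, truth = generate(design)
    ppi = generate_ppi(corpus, design)
    paths = {
        "disease_genes": out / "disease_genes.tsv",
        "drug_targets": out / "drug_targets.tsv",
        "indications": out / "indications.tsv",
        "ppi": out / "ppi.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_associations(paths["disease_genes"], corpus.diseases, corpus.names)
    write_associations(paths["drug_targets"], corpus.drugs, corpus.names)
    write_indications(paths["indications"], corpus.known_indications)
    write_ppi(paths["ppi"], ppi)
    for lib in libraries:
        p = out / f"{lib.category}.gmt"
        write_gmt(p, lib)
        paths[lib.category] = p
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "module_diseases": [list(t) for t in truth.module_diseases],
                "module_drugs": [list(t) for t in truth.module_drugs],
                "known_indications": sorted(map(list, truth.known_indications)),
                "expected_candidates": sorted(map(list, truth.expected_candidates)),
            },
            indent=1,
        )
        + "\n"
    )
    return paths
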