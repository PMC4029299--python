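"""Annotation tables: disease-gene / drug-target sets, indications, gene-set
libraries, and protein-interaction edge lists.

All readers accept plain tab-separated text.  Association tables carry
``entity_id <TAB> gene_id [<TAB> entity_name]``; indication tables carry
``disease_id <TAB> drug_id``; feature libraries use the GMT dialect
(``feature_id <TAB> description <TAB> gene ...``); PPI files carry one gene
pair per line.  Parsing is lenient by default: malformed rows are skipped and
counted; ``strict=True`` turns them into errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

#: recognised feature-library categories
CATEGORIES = ("biological_process", "pathway", "phenotype")

#: the gene-similarity layer label (the three feature categories are the rest)
GENE_LAYER = "gene"

#: all four similarity-layer labels, in canonical order
LAYERS = (GENE_LAYER,) + CATEGORIES


class ParseError(ValueError):
    """A malformed input row in strict mode, or an unusable file."""


@dataclass(frozen=True)
class AnnotationCorpus:
    """Gene annotations for diseases and drugs plus known indications.

    ``diseases`` and ``drugs`` map entity ids to non-empty gene-id sets;
    ``names`` maps any entity id to a display name; ``known_indications``
    holds (disease_id, drug_id) pairs restricted to loaded entities;
    ``gene_universe`` is the union of all annotated genes unless overridden.
    """

    diseases: dict[str, frozenset[str]]
    drugs: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    known_indications: frozenset[tuple[str, str]] = frozenset()
    gene_universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        clash = set(self.diseases) & set(self.drugs)
        if clash:
            raise ValueError(
                f"entity ids shared between disease and drug namespaces: {sorted(clash)[:5]}"
            )
        if not self.gene_universe:
            universe = frozenset().union(*self.diseases.values(), *self.drugs.values(), frozenset())
            object.__setattr__(self, "gene_universe", universe)

    @property
    def node_types(self) -> dict[str, str]:
        """Map every entity id to ``"disease"`` or ``"drug"``."""
        types = {d: "disease" for d in self.diseases}
        types.update({r: "drug" for r in self.drugs})
        return types

    def name_of(self, entity_id: str) -> str:
        return self.names.get(entity_id, entity_id)


@dataclass(frozen=True)
class FeatureLibrary:
    """A named-gene-set library for one feature category."""

    category: str
    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        for fid, genes in self.sets.items():
            if not genes:
                raise ValueError(f"feature {fid!r} has an empty gene set")

    @property
    def gene_union(self) -> frozenset[str]:
        return frozenset().union(*self.sets.values()) if self.sets else frozenset()


@dataclass(frozen=True)
class PpiGraph:
    """Undirected simple protein-interaction graph over gene ids."""

    edges: frozenset[frozenset[str]]
    nodes: frozenset[str]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


# ---------------------------------------------------------------------------
# readers


def _rows(path: str | Path, min_fields: int, strict: bool) -> Iterable[list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields or any(not f.strip() for f in fields[:min_fields]):
                if strict:
                    raise ParseError(f"{path}:{lineno}: malformed row {line!r}")
                skipped += 1
                continue
            yield [f.strip() for f in fields]
    if skipped:
        log.warning("%s: skipped %d malformed rows", path, skipped)


def load_associations(
    path: str | Path, entity_kind: str = "disease", strict: bool = False
) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Read an entity-gene association table.

    Returns ``(gene_sets, names)``: deduplicated gene sets per entity (zero-gene
    entities cannot arise from the row format) and any display names found in
    the optional third column.
    """
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_rows = 0
    for fields in _rows(path, 2, strict):
        entity, gene = fields[0], fields[1]
        sets.setdefault(entity, set()).add(gene)
        if len(fields) >= 3 and fields[2]:
            names[entity] = fields[2]
        n_rows += 1
    if n_rows == 0:
        log.warning("%s: no %s association rows found", path, entity_kind)
    log.info("%s: %d rows -> %d %s entities", path, n_rows, len(sets), entity_kind)
    return {e: frozenset(g) for e, g in sets.items()}, names


def load_indications(path: str | Path, strict: bool = False) -> set[tuple[str, str]]:
    """Read a known-indication table (disease_id, drug_id)."""
    pairs = {(f[0], f[1]) for f in _rows(path, 2, strict)}
    log.info("%s: %d known indications", path, len(pairs))
    return pairs


def load_gmt(path: str | Path, category: str, strict: bool = False) -> FeatureLibrary:
    """Read a GMT gene-set library: id, description, then >=1 gene per line."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for fields in _rows(path, 3, strict):
        fid, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if not genes:
            if strict:
                raise ParseError(f"{path}: feature {fid!r} has no genes")
            log.warning("%s: feature %s has no genes; skipped", path, fid)
            continue
        if fid in sets:
            log.warning("%s: duplicate feature id %s; later line overwrites", path, fid)
        sets[fid] = frozenset(genes)
        names[fid] = desc
    if not sets:
        raise ParseError(f"empty library: {path}")
    return FeatureLibrary(category=category, sets=sets, names=names)


def load_ppi(path: str | Path, strict: bool = False, keep_isolated: bool = False) -> PpiGraph:
    """Read a PPI edge list; self-loops and duplicate edges are dropped."""
    edges: set[frozenset[str]] = set()
    n_loops = n_dup = 0
    for fields in _rows(path, 2, strict):
        a, b = fields[0], fields[1]
        if a == b:
            n_loops += 1
            continue
        e = frozenset((a, b))
        if e in edges:
            n_dup += 1
        edges.add(e)
    if n_loops or n_dup:
        log.info("%s: dropped %d self-loops, %d duplicate edges", path, n_loops, n_dup)
    nodes = frozenset().union(*edges) if edges else frozenset()
    return PpiGraph(edges=frozenset(edges), nodes=nodes)


def load_id_map(path: str | Path, strict: bool = False) -> dict[str, str]:
    """Read a two-column id cross-mapping (secondary_id, primary_id)."""
    return {f[0]: f[1] for f in _rows(path, 2, strict)}


def merge_target_sources(
    primary: Mapping[str, frozenset[str]],
    secondary: Mapping[str, frozenset[str]],
    id_map: Mapping[str, str],
    create_missing: bool = False,
) -> dict[str, frozenset[str]]:
    """Union a secondary target source into the primary namespace via id_map.

    Secondary entities without a mapping are ignored (counted).  Mapped ids
    absent from ``primary`` create new entities only if ``create_missing``.
    """
    merged = {e: set(g) for e, g in primary.items()}
    n_unmapped = n_skipped = 0
    for sec_id, genes in secondary.items():
        prim_id = id_map.get(sec_id)
        if prim_id is None:
            n_unmapped += 1
            continue
        if prim_id not in merged:
            if not create_missing:
                n_skipped += 1
                continue
            merged[prim_id] = set()
        merged[prim_id] |= genes
    if n_unmapped or n_skipped:
        log.info(
            "target merge: %d secondary entities unmapped, %d mapped to unknown primary ids",
            n_unmapped,
            n_skipped,
        )
    return {e: frozenset(g) for e, g in merged.items()}


def build_corpus(
    diseases: Mapping[str, frozenset[str]],
    drugs: Mapping[str, frozenset[str]],
    names: Mapping[str, str] | None = None,
    known_indications: Iterable[tuple[str, str]] = (),
    gene_universe: Iterable[str] | None = None,
) -> AnnotationCorpus:
    """Assemble a validated corpus: drop zero-gene entities and indications
    that reference unloaded entities, with logged counts."""
    dis = {e: g for e, g in diseases.items() if g}
    dru = {e: g for e, g in drugs.items() if g}
    n_dropped = (len(diseases) - len(dis)) + (len(drugs) - len(dru))
    if n_dropped:
        log.info("dropped %d zero-gene entities", n_dropped)
    indications = set(known_indications)
    kept = {(d, r) for d, r in indications if d in dis and r in dru}
    if len(kept) < len(indications):
        log.info("dropped %d indications referencing unloaded entities", len(indications) - len(kept))
    return AnnotationCorpus(
        diseases=dict(dis),
        drugs=dict(dru),
        names=dict(names or {}),
        known_indications=frozenset(kept),
        gene_universe=frozenset(gene_universe) if gene_universe else frozenset(),
    )


def load_corpus(
    disease_path: str | Path,
    drug_path: str | Path,
    indication_path: str | Path | None = None,
    secondary_target_path: str | Path | None = None,
    id_map_path: str | Path | None = None,
    strict: bool = False,
) -> AnnotationCorpus:
    """Load a full corpus from association tables, optionally augmenting drug
    targets from a secondary source through an id mapping."""
    diseases, dnames = load_associations(disease_path, "disease", strict)
    drugs, rnames = load_associations(drug_path, "drug", strict)
    if secondary_target_path is not None:
        secondary, _ = load_associations(secondary_target_path, "drug", strict)
        id_map = load_id_map(id_map_path, strict) if id_map_path else {}
        drugs = merge_target_sources(drugs, secondary, id_map)
    indications = load_indications(indication_path, strict) if indication_path else set()
    return build_corpus(diseases, drugs, {**dnames, **rnames}, indications)


def enrichment_universe(corpus: AnnotationCorpus, libraries: Iterable[FeatureLibrary]) -> frozenset[str]:
    """Default enrichment background: all genes seen in any entity annotation
    or any feature library."""
    return frozenset(corpus.gene_universe).union(*(lib.gene_union for lib in libraries), frozenset())


# ---------------------------------------------------------------------------
# writers (round-trip the dialects the readers accept)


def write_associations(path: str | Path, sets: Mapping[str, frozenset[str]], names: Mapping[str, str] | None = None) -> None:
    names = names or {}
    with open(path, "w") as fh:
        for entity in sorted(sets):
            for gene in sorted(sets[entity]):
                name = names.get(entity)
                fh.write(f"{entity}\t{gene}" + (f"\t{name}" if name else "") + "\n")


def write_indications(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for d, r in sorted(pairs):
            fh.write(f"{d}\t{r}\n")


def write_gmt(path: str | Path, library: FeatureLibrary) -> None:
    with open(path, "w") as fh:
        for fid in sorted(library.sets):
            desc = library.names.get(fid, fid)
            genes = "\t".join(sorted(library.sets[fid]))
            fh.write(f"{fid}\t{desc}\t{genes}\n")


def write_ppi(path: str | Path, ppi: PpiGraph) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in ppi.edges):
            fh.write(f"{a}\t{b}\n")
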