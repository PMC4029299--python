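"""Per-entity gene-set over-representation profiles.

Each disease or drug gene set is tested against every feature set of each
library with a one-sided hypergeometric test; features whose Bonferroni-
corrected p-value is at most ``alpha`` form the entity's enrichment profile
for that category.  These profiles feed the feature-based similarity layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .corpus import AnnotationCorpus, FeatureLibrary

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentProfile:
    """Significantly enriched features of one entity, per category.

    ``enriched`` maps category -> enriched feature-id set; ``pvalues`` maps
    category -> feature id -> (raw p, Bonferroni-corrected p) for every
    enriched feature (kept for reporting).
    """

    entity_id: str
    enriched: dict[str, frozenset[str]] = field(default_factory=dict)
    pvalues: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def features(self, category: str) -> frozenset[str]:
        return self.enriched.get(category, frozenset())


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` genes of an ``n``-gene query fall in a feature set of size ``K``
    drawn against a universe of ``N`` genes.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_entity(
    genes: frozenset[str] | set[str],
    library: FeatureLibrary,
    universe: frozenset[str],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, tuple[float, float]]:
    """Enriched features of one gene set against one library.

    Returns feature id -> (raw p, corrected p) for features with corrected
    p <= alpha.  The Bonferroni multiplier is the number of library features
    with a non-empty universe intersection; zero-overlap features are never
    enriched.
    """
    if not universe:
        raise ValueError("empty enrichment universe")
    query = frozenset(genes) & universe
    if len(query) < len(frozenset(genes)):
        log.debug("query trimmed to universe: %d -> %d genes", len(genes), len(query))
    n, N = len(query), len(universe)
    testable = {fid: fset & universe for fid, fset in library.sets.items()}
    testable = {fid: fset for fid, fset in testable.items() if fset}
    M = len(testable)
    out: dict[str, tuple[float, float]] = {}
    if n == 0 or M == 0:
        return out
    for fid, fset in testable.items():
        k = len(query & fset)
        if k == 0:
            continue
        raw = hypergeom_tail(k, len(fset), n, N)
        corrected = min(1.0, raw * M)
        if corrected <= alpha:
            out[fid] = (raw, corrected)
    return out


def profile_corpus(
    corpus: AnnotationCorpus,
    libraries: Iterable[FeatureLibrary],
    alpha: float = DEFAULT_ALPHA,
    universe: frozenset[str] | None = None,
) -> dict[str, EnrichmentProfile]:
    """One enrichment profile per corpus entity (diseases and drugs).

    ``universe`` defaults to the corpus gene universe; pass
    :func:`hetrepo.corpus.enrichment_universe` output to include library genes
    in the background.
    """
    libraries = list(libraries)
    if not libraries:
        raise ValueError("at least one feature library is required")
    universe = universe if universe is not None else corpus.gene_universe
    profiles: dict[str, EnrichmentProfile] = {}
    all_entities = {**corpus.diseases, **corpus.drugs}
    for entity_id in sorted(all_entities):
        genes = all_entities[entity_id]
        enriched: dict[str, frozenset[str]] = {}
        pvals: dict[str, dict[str, tuple[float, float]]] = {}
        for lib in libraries:
            hits = enrich_entity(genes, lib, universe, alpha)
            enriched[lib.category] = frozenset(hits)
            pvals[lib.category] = hits
        if not any(enriched.values()):
            log.debug("entity %s has an all-empty enrichment profile", entity_id)
        profiles[entity_id] = EnrichmentProfile(entity_id, enriched, pvals)
    return profiles


def feature_attribute_map(
    profiles: Mapping[str, EnrichmentProfile], category: str
) -> dict[str, frozenset[str]]:
    """Entity -> enriched-feature-id set for one category (layer input)."""
    return {e: p.features(category) for e, p in profiles.items()}


def write_profiles(path: str | Path, profiles: Mapping[str, EnrichmentProfile]) -> None:
    """TSV export: entity_id, category, feature_id, raw_p, corrected_p."""
    with open(path, "w") as fh:
        fh.write("entity_id\tcategory\tfeature_id\traw_p\tcorrected_p\n")
        for entity_id in sorted(profiles):
            prof = profiles[entity_id]
            for category in sorted(prof.pvalues):
                for fid in sorted(prof.pvalues[category]):
                    raw, corr = prof.pvalues[category][fid]
                    fh.write(f"{entity_id}\t{category}\t{fid}\t{raw:.6g}\t{corr:.6g}\n")


def read_profiles(path: str | Path) -> dict[str, EnrichmentProfile]:
    """Read the TSV written by :func:`write_profiles`."""
    enriched: dict[str, dict[str, set[str]]] = {}
    pvals: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("entity_id"):
            raise ValueError(f"{path}: missing profile header")
        for line in fh:
            entity, category, fid, raw, corr = line.rstrip("\n").split("\t")
            enriched.setdefault(entity, {}).setdefault(category, set()).add(fid)
            pvals.setdefault(entity, {}).setdefault(category, {})[fid] = (float(raw), float(corr))
    return {
        e: EnrichmentProfile(
            e,
            {c: frozenset(s) for c, s in enriched[e].items()},
            pvals[e],
        )
        for e in enriched
    }
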