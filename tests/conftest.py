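import types

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from hetrepo.corpus import CATEGORIES, enrichment_universe
from hetrepo.enrich import feature_attribute_map, profile_corpus
from hetrepo.network import GENE_LAYER, assemble_network, build_layer
from hetrepo.simulate import PlantedDesign, generate, generate_ppi

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=list(HealthCheck)
)
settings.load_profile("suite")


def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")], weight=1
    )
    return g


def bridged_triangles() -> nx.Graph:
    g = two_triangles()
    g.add_edge("c", "x", weight=1)
    return g


@pytest.fixture(scope="session")
def default_design() -> PlantedDesign:
    return PlantedDesign()


@pytest.fixture(scope="session")
def bundle(default_design):
    """The default planted-module fixture, fully processed to a network."""
    corpus, libraries, truth = generate(default_design)
    universe = enrichment_universe(corpus, libraries)
    profiles = profile_corpus(corpus, libraries, 0.05, universe)
    attr_maps = {GENE_LAYER: {**corpus.diseases, **corpus.drugs}}
    for cat in CATEGORIES:
        attr_maps[cat] = feature_attribute_map(profiles, cat)
    layers = [build_layer(attr_maps[lab], lab, 0.5) for lab in attr_maps]
    net = assemble_network(layers, corpus.node_types)
    return types.SimpleNamespace(
        design=default_design,
        corpus=corpus,
        libraries=libraries,
        truth=truth,
        profiles=profiles,
        layers=layers,
        net=net,
        ppi=generate_ppi(corpus, default_design),
    )
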