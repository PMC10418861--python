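"""Shared fixtures: the 5-edge toy graph, random graph builders, and the
hub-score regression fixture path."""

from pathlib import Path

import numpy as np
import pytest

from hetepath import ConceptNode, KnowledgeGraph, MetaPath, Predication, parse_metapath
from hetepath.metapaths import FORWARD, REVERSE, MetaPathStep

FIXTURE_DIR = Path(__file__).parent / "data"

# toy graph "G1": two drugs, two genes, one disease
G1_NODES = [
    ("C9000001", "d1", "PHSU"),
    ("C9000002", "d2", "PHSU"),
    ("C9000011", "g1", "GNGM"),
    ("C9000012", "g2", "GNGM"),
    ("C9000021", "D", "DSYN"),
]
G1_EDGES = [
    ("C9000001", "AFFECTS", "C9000011"),
    ("C9000001", "AFFECTS", "C9000012"),
    ("C9000002", "AFFECTS", "C9000011"),
    ("C9000011", "ASSOCIATED_WITH", "C9000021"),
    ("C9000012", "ASSOCIATED_WITH", "C9000021"),
]
D1, D2, G1N1, G1N2, DISEASE = (cui for cui, _, _ in G1_NODES)


def build_g1() -> KnowledgeGraph:
    g = KnowledgeGraph()
    for cui, name, st in G1_NODES:
        g.add_node(ConceptNode(cui, name, st))
    for s, p, o in G1_EDGES:
        g.add_edge(Predication(s, p, o))
    return g


@pytest.fixture
def g1() -> KnowledgeGraph:
    return build_g1()


@pytest.fixture
def g1_mp() -> MetaPath:
    return parse_metapath("PHSU-[AFFECTS>]-GNGM-[ASSOCIATED_WITH>]-DSYN")


@pytest.fixture
def hub_scores_path() -> Path:
    return FIXTURE_DIR / "hub_scores_fixture.tsv"


SEMTYPES = ("PHSU", "GNGM", "DSYN", "AAPP")
PREDICATES = ("TREATS", "AFFECTS", "ASSOCIATED_WITH", "INTERACTS_WITH", "CAUSES")


def random_graph(seed: int, n_nodes: int = 30, n_edges: int = 60) -> KnowledgeGraph:
    """Small random typed multigraph for property tests (deterministic)."""
    rng = np.random.default_rng(seed)
    g = KnowledgeGraph()
    cuis = []
    for i in range(n_nodes):
        cui = f"C{9100000 + i}"
        st = SEMTYPES[int(rng.integers(len(SEMTYPES)))]
        g.add_node(ConceptNode(cui, f"n{i}", st))
        cuis.append(cui)
    for _ in range(n_edges):
        s, o = rng.choice(n_nodes, size=2, replace=False)
        p = PREDICATES[int(rng.integers(len(PREDICATES)))]
        g.add_edge(
            Predication(cuis[s], p, cuis[o], support_count=int(rng.integers(1, 4)))
        )
    return g


def random_metapath_with_instance(
    graph: KnowledgeGraph, seed: int, length: int
) -> tuple[str, str, MetaPath] | None:
    """Sample a random walk and return (start, end, its type-level metapath);
    None when the sampled start has no walk of the wanted length."""
    rng = np.random.default_rng(seed)
    adjacency = graph.adjacency_index()
    nodes = sorted(adjacency)
    start = nodes[int(rng.integers(len(nodes)))]
    node, steps = start, []
    for _ in range(length):
        entries = adjacency[node]
        if not entries:
            return None
        nbr, predicate, is_reverse, nbr_semtype = entries[int(rng.integers(len(entries)))]
        steps.append(
            MetaPathStep(
                from_semtype=graph.semtype_of(node),
                predicate=predicate,
                to_semtype=nbr_semtype,
                direction=REVERSE if is_reverse else FORWARD,
            )
        )
        node = nbr
    return start, node, MetaPath(tuple(steps))
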