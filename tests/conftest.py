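import math

import networkx as nx
import numpy as np
import pytest

from genelink import CorpusConfig, GeneCatalog, generate_corpus


def floyd_warshall_oracle(graph: nx.Graph) -> dict[tuple[str, str], float]:
    """Independent all-pairs shortest-path oracle (plain Floyd-Warshall)."""
    nodes = sorted(graph.nodes())
    dist = {(u, v): (0.0 if u == v else math.inf) for u in nodes for v in nodes}
    for u, v, data in graph.edges(data=True):
        w = data["weight"]
        if w < dist[(u, v)]:
            dist[(u, v)] = dist[(v, u)] = w
    for k in nodes:
        for i in nodes:
            dik = dist[(i, k)]
            if math.isinf(dik):
                continue
            for j in nodes:
                alt = dik + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.15) -> nx.Graph:
    """Random graph with dyadic-rational weights (multiples of 1/256).

    Dyadic weights make path sums exact in binary floating point whatever
    the summation order, so shortest-path results can be compared to an
    independent algorithm with strict equality.
    """
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(
                    nodes[i],
                    nodes[j],
                    weight=float(rng.integers(0, 257)) / 256.0,
                    kind="similarity" if rng.random() < 0.5 else "operon",
                )
    return g


@pytest.fixture
def tiny_catalog() -> GeneCatalog:
    return GeneCatalog({"GA": ["a1", "a2", "a3"], "GB": ["b1", "b2", "b3"]})


@pytest.fixture
def bridge_motif():
    """Minimal operon-bridge topology: A ~sim~ A', A'-B' operon, B' ~sim~ B.

    A and B sit in the query genome with no mutual similarity; A' and B'
    share an operon in a third-party genome.
    """
    g = nx.Graph()
    g.add_node("A", genome="Q", locus=0)
    g.add_node("B", genome="Q", locus=5)
    g.add_node("Ap", genome="T", locus=0)
    g.add_node("Bp", genome="T", locus=1)
    g.add_edge("A", "Ap", weight=0.3, kind="similarity")
    g.add_edge("Ap", "Bp", weight=0.05, kind="operon")
    g.add_edge("Bp", "B", weight=0.4, kind="similarity")
    return g


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced corpus exercising both planted-group flavors quickly."""
    cfg = CorpusConfig(
        n_genomes=8,
        genes_per_genome=40,
        n_families=12,
        n_planted_groups=4,
        bridge_fraction=0.5,
        rng_seed=11,
    )
    return generate_corpus(cfg)
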