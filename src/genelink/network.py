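"""Construction of the weighted gene functional network.

Every catalogued gene is a node.  Two transformed evidence channels supply
edge weights in [0, 1], where *smaller* means *more strongly linked*:

* sequence similarity: ``w_s(E) = 1 + log10(E) / 185``, with the BLAST
  e-value ``E`` clamped below at 1e-185 (BLAST reports smaller e-values as
  0) and the result clamped into [0, 1].  185 is the normalization constant
  tied to that floor, so ``E = 1`` gives weight 1 (barely similar) and
  ``E <= 1e-185`` gives weight 0 (essentially identical).
* operon context: ``w_o(P) = 1 - P`` for the probability ``P`` that an
  adjacent gene pair shares an operon.

When a pair has both kinds of evidence the single retained edge carries the
smaller (stronger) weight; shortest-path distances treat both kinds
interchangeably, so merging by minimum is distance-equivalent to keeping
parallel edges.

The module also provides the degree-preserving permutation control used to
show that predictive signal lives in the network topology.
"""

from __future__ import annotations

import math
from typing import Iterable

import networkx as nx
import numpy as np

from .io import GeneCatalog, OperonPairRecord, SimilarityRecord, ValidationError

#: e-values at or below this floor are reported as 0 by BLAST
EVALUE_FLOOR_EXPONENT = 185

SIMILARITY = "similarity"
OPERON = "operon"


def similarity_weight(evalue: float, clamp_exponent: int = EVALUE_FLOOR_EXPONENT) -> float:
    """Transform a BLAST e-value into an edge weight in [0, 1].

    Strictly decreasing in -log10(E) on (10**-clamp_exponent, 1]; e-values
    of 0 (BLAST's underflow report) are treated as the floor and map to 0.
    """
    if evalue < 0:
        raise ValueError(f"negative e-value {evalue!r}")
    floor = 10.0 ** (-clamp_exponent)
    e = max(evalue, floor)
    w = 1.0 + math.log10(e) / clamp_exponent
    return min(1.0, max(0.0, w))


def operon_weight(probability: float) -> float:
    """Transform a same-operon probability into an edge weight in [0, 1]."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"operon probability {probability!r} outside [0, 1]")
    return 1.0 - probability


def build_network(
    catalog: GeneCatalog,
    sims: Iterable[SimilarityRecord] = (),
    operons: Iterable[OperonPairRecord] = (),
    max_evalue: float = 1e-3,
    clamp_exponent: int = EVALUE_FLOOR_EXPONENT,
) -> nx.Graph:
    """Build the functional network from similarity and operon evidence.

    Nodes are all catalog genes (isolated genes retained) with ``genome``
    and ``locus`` attributes.  For each unordered gene pair the candidate
    similarity weight uses the minimum e-value across both BLAST directions;
    the retained edge carries the smaller of the similarity and operon
    candidate weights and a ``kind`` label recording which evidence won
    (similarity on exact ties).  The result is independent of input record
    order.
    """
    graph = nx.Graph()
    for genome_id, genes in catalog.genomes.items():
        for locus, g in enumerate(genes):
            graph.add_node(g, genome=genome_id, locus=locus)

    best_evalue: dict[tuple[str, str], float] = {}
    for r in sims:
        for g in (r.query_id, r.subject_id):
            if g not in catalog:
                raise ValidationError(f"similarity record names unknown gene {g!r}")
        if r.query_id == r.subject_id or r.evalue > max_evalue:
            continue
        key = (r.query_id, r.subject_id) if r.query_id < r.subject_id else (r.subject_id, r.query_id)
        prev = best_evalue.get(key)
        if prev is None or r.evalue < prev:
            best_evalue[key] = r.evalue

    best_prob: dict[tuple[str, str], float] = {}
    for r in operons:
        for g in (r.gene_a, r.gene_b):
            if g not in catalog:
                raise ValidationError(f"operon record names unknown gene {g!r}")
        key = (r.gene_a, r.gene_b) if r.gene_a < r.gene_b else (r.gene_b, r.gene_a)
        prev = best_prob.get(key)
        if prev is None or r.probability > prev:
            best_prob[key] = r.probability

    for key in best_evalue.keys() | best_prob.keys():
        w_s = (
            similarity_weight(best_evalue[key], clamp_exponent)
            if key in best_evalue
            else math.inf
        )
        w_o = operon_weight(best_prob[key]) if key in best_prob else math.inf
        if w_s <= w_o:
            graph.add_edge(*key, weight=w_s, kind=SIMILARITY)
        else:
            graph.add_edge(*key, weight=w_o, kind=OPERON)
    return graph


def permute_network(
    network: nx.Graph, rng_seed: int, swap_factor: int = 10
) -> nx.Graph:
    """Degree-preserving rewiring by repeated double-edge swaps.

    Attempts ``swap_factor * |E|`` swaps; each swap replaces edges (u, v)
    and (x, y) by (u, x) and (v, y) when neither new edge is a self-loop or
    already present.  Node set and degree sequence are preserved exactly;
    each surviving edge carries the (weight, kind) payload of one parent
    edge.  Deterministic given *rng_seed*.  Networks with fewer than two
    edges are returned as unchanged copies.
    """
    out = network.copy()
    edges = [(u, v, dict(d)) for u, v, d in out.edges(data=True)]
    if len(edges) < 2:
        return out
    rng = np.random.default_rng(rng_seed)
    n_attempts = swap_factor * len(edges)
    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        u, v, d_uv = edges[i]
        x, y, d_xy = edges[j]
        if rng.integers(0, 2):
            x, y = y, x
        # new edges: (u, x) with payload of (u, v); (v, y) with payload of (x, y)
        if u == x or v == y:
            continue
        if out.has_edge(u, x) or out.has_edge(v, y):
            continue
        out.remove_edge(u, v)
        out.remove_edge(x, y)
        out.add_edge(u, x, **d_uv)
        out.add_edge(v, y, **d_xy)
        edges[i] = (u, x, d_uv)
        edges[j] = (v, y, d_xy)
    return out


def network_hash(network: nx.Graph) -> int:
    """Order-independent fingerprint of nodes and weighted, labelled edges."""
    node_part = frozenset(network.nodes())
    edge_part = frozenset(
        (min(u, v), max(u, v), d["weight"], d["kind"])
        for u, v, d in network.edges(data=True)
    )
    return hash((node_part, edge_part))


def edge_multiset(network: nx.Graph) -> set[tuple[str, str, float, str]]:
    """Canonical edge set for equality checks in tests and restore contracts."""
    return {
        (min(u, v), max(u, v), d["weight"], d["kind"])
        for u, v, d in network.edges(data=True)
    }
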