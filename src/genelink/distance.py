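"""Functional distances, genome-wide ranking and path explanations.

The functional distance between a seed gene and a candidate is the weighted
shortest-path value between their nodes (Dijkstra; weights are non-negative
by construction).  With several seed genes the per-seed distances are summed
and averaged; an unreachable seed makes the aggregate infinite.  Given a
seed set, every other gene of a target genome is ranked by ascending
aggregate distance — the top of the list is the predicted functional
linkage.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import GeneCatalog

#: returned when no path connects a pair
UNREACHABLE = math.inf

TIE_POLICY = "lexicographic"


@dataclass
class RankingResult:
    """Candidates of one genome ordered by functional distance to a seed set."""

    seed_set: frozenset[str]
    target_genome: str
    ranked: list[tuple[str, float]]
    tie_policy: str = TIE_POLICY
    path_edges: dict[str, int] | None = None

    def top(self, k: int = 1) -> list[tuple[str, float]]:
        return self.ranked[:k]

    def rank_of(self, gene_id: str) -> int:
        for i, (g, _) in enumerate(self.ranked, start=1):
            if g == gene_id:
                return i
        raise KeyError(gene_id)

    def iter_rows(self):
        for gene_id, dist in self.ranked:
            n = None if self.path_edges is None else self.path_edges.get(gene_id)
            yield gene_id, dist, n


@dataclass
class PathStep:
    gene_from: str
    gene_to: str
    kind: str
    weight: float
    genome_to: str


@dataclass
class PathExplanation:
    """One shortest path from seed to candidate, annotated step by step."""

    nodes: list[str]
    steps: list[PathStep]
    total_distance: float

    def has_kind(self, kind: str) -> bool:
        return any(s.kind == kind for s in self.steps)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": self.nodes,
                "total_distance": self.total_distance,
                "steps": [
                    {
                        "from": s.gene_from,
                        "to": s.gene_to,
                        "kind": s.kind,
                        "weight": s.weight,
                        "genome_to": s.genome_to,
                    }
                    for s in self.steps
                ],
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"path {self.nodes[0]} -> {self.nodes[-1]}  (distance {self.total_distance:.6g})"]
        for s in self.steps:
            lines.append(
                f"  {s.gene_from} --[{s.kind} w={s.weight:.6g}]--> "
                f"{s.gene_to} ({s.genome_to})"
            )
        return "\n".join(lines)


def functional_distance(network: nx.Graph, seed: str, candidate: str) -> float:
    """Weighted shortest-path distance; :data:`UNREACHABLE` if no path exists."""
    for g in (seed, candidate):
        if g not in network:
            raise KeyError(f"unknown gene {g!r}")
    if seed == candidate:
        return 0.0
    try:
        return nx.dijkstra_path_length(network, seed, candidate)
    except nx.NetworkXNoPath:
        return UNREACHABLE


def seed_distance_maps(
    network: nx.Graph, seeds: Iterable[str]
) -> dict[str, dict[str, float]]:
    """Single-source Dijkstra distances from each seed (missing key = unreachable)."""
    maps = {}
    for s in seeds:
        if s not in network:
            raise KeyError(f"unknown seed gene {s!r}")
        maps[s] = nx.single_source_dijkstra_path_length(network, s)
    return maps


def aggregate_distance(network: nx.Graph, seeds: Iterable[str], candidate: str) -> float:
    """Mean functional distance from a seed set; any unreachable seed gives infinity."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    total = 0.0
    for s in seeds:
        d = functional_distance(network, s, candidate)
        if math.isinf(d):
            return UNREACHABLE
        total += d
    return total / len(seeds)


def _aggregate_from_maps(maps: Mapping[str, Mapping[str, float]], candidate: str) -> float:
    total = 0.0
    for dmap in maps.values():
        d = dmap.get(candidate)
        if d is None:
            return UNREACHABLE
        total += d
    return total / len(maps)


def rank_genes(
    network: nx.Graph,
    seeds: Iterable[str],
    target_genome: str,
    catalog: GeneCatalog,
    exclude: Iterable[str] = (),
) -> RankingResult:
    """Rank every gene of *target_genome* (minus seeds and *exclude*) by
    mean functional distance to the seed set, ascending; ties broken
    lexicographically by gene id."""
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("empty seed set")
    if target_genome not in catalog.genomes:
        raise KeyError(f"unknown genome {target_genome!r}")
    skip = set(seeds) | set(exclude)
    candidates = [g for g in catalog.genomes[target_genome] if g not in skip]
    maps = seed_distance_maps(network, seeds)
    scored = [(g, _aggregate_from_maps(maps, g)) for g in candidates]
    scored.sort(key=lambda t: (t[1], t[0]))
    return RankingResult(frozenset(seeds), target_genome, scored)


def _dijkstra_predecessors(
    network: nx.Graph, source: str
) -> tuple[dict[str, float], dict[str, str]]:
    """Dijkstra with smallest-gene-id predecessor tie-break (deterministic paths)."""
    dist: dict[str, float] = {source: 0.0}
    pred: dict[str, str] = {}
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in sorted(network.neighbors(u)):
            nd = d + network[u][v]["weight"]
            old = dist.get(v)
            if old is None or nd < old:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif nd == old and v not in done and u < pred.get(v, u):
                pred[v] = u
    return dist, pred


def explain_path(network: nx.Graph, seed: str, candidate: str) -> PathExplanation:
    """Trace one shortest path, annotating each step's edge kind, weight and
    the genome of the gene it enters.  Raises ``nx.NetworkXNoPath`` when the
    pair is disconnected."""
    for g in (seed, candidate):
        if g not in network:
            raise KeyError(f"unknown gene {g!r}")
    dist, pred = _dijkstra_predecessors(network, seed)
    if candidate not in dist:
        raise nx.NetworkXNoPath(f"no path between {seed!r} and {candidate!r}")
    nodes = [candidate]
    while nodes[-1] != seed:
        nodes.append(pred[nodes[-1]])
    nodes.reverse()
    steps = []
    for a, b in zip(nodes, nodes[1:]):
        data = network[a][b]
        steps.append(
            PathStep(a, b, data["kind"], data["weight"], network.nodes[b].get("genome", ""))
        )
    return PathExplanation(nodes, steps, dist[candidate])
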