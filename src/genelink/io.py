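"""Readers and writers for every external file format the tool touches.

No science lives here, only faithful parsing with validation.  The dialects:

* BLAST tabular (``-outfmt 6``): 12 tab-separated columns; only query id
  (col 1), subject id (col 2) and e-value (col 11) are consumed.
* Operon pair table: TSV with header ``genome_id  gene_a  gene_b  probability``,
  one adjacent gene pair per row with its same-operon probability.
* Gene catalog: TSV with header ``genome_id  gene_id  locus_index``; locus
  index gives chromosomal order within the genome.
* Annotation groups: headerless two-column TSV ``group_id<TAB>gene_id``
  (KEGG-style EC/pathway membership lists).
* Network edge list: TSV with header ``gene_a  gene_b  weight  kind``;
  weights are serialized with ``repr`` so round-trips are bit-exact.
* Ranking: TSV with header ``rank  gene_id  distance  n_path_edges``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

INFINITY_TOKEN = "inf"


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a documented invariant."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class SimilarityRecord:
    """One retained BLAST hit: the e-value E between two genes."""

    query_id: str
    subject_id: str
    evalue: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValidationError("gene identifiers must be non-empty")
        if self.evalue < 0:
            raise ValidationError(f"negative e-value {self.evalue!r}")


@dataclass(frozen=True)
class OperonPairRecord:
    """An adjacent gene pair with its probability P of sharing an operon."""

    genome_id: str
    gene_a: str
    gene_b: str
    probability: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair {self.gene_a!r} in operon record")
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"operon probability {self.probability!r} outside [0, 1]"
            )


@dataclass
class GeneCatalog:
    """Mapping genome id -> ordered gene identifiers (chromosomal order).

    Every gene identifier occurs in exactly one genome; per-genome order has
    no duplicates.
    """

    genomes: dict[str, list[str]]
    _genome_of: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        genome_of: dict[str, str] = {}
        for genome_id, genes in self.genomes.items():
            for g in genes:
                if g in genome_of:
                    raise ValidationError(
                        f"gene {g!r} occurs in both {genome_of[g]!r} and {genome_id!r}"
                    )
                genome_of[g] = genome_id
        self._genome_of = genome_of

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genome_of

    def __len__(self) -> int:
        return len(self._genome_of)

    def genome_of(self, gene_id: str) -> str:
        try:
            return self._genome_of[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def locus_of(self, gene_id: str) -> int:
        return self.genomes[self.genome_of(gene_id)].index(gene_id)

    def all_genes(self) -> list[str]:
        return [g for genes in self.genomes.values() for g in genes]


@dataclass
class AnnotationSet:
    """Named functional groups (EC numbers / pathway ids) of gene identifiers.

    Groups of fewer than three genes are retained but flagged unusable for
    leave-one-out validation, which needs at least two seeds per run.
    """

    groups: dict[str, set[str]]

    MIN_USABLE = 3

    def usable_groups(self) -> dict[str, set[str]]:
        return {k: v for k, v in self.groups.items() if len(v) >= self.MIN_USABLE}

    def unusable_groups(self) -> dict[str, set[str]]:
        return {k: v for k, v in self.groups.items() if len(v) < self.MIN_USABLE}


# ---------------------------------------------------------------------------
# readers


def read_blast_tabular(path: str | Path, max_evalue: float = 1e-3) -> list[SimilarityRecord]:
    """Read BLAST ``-outfmt 6`` output, keeping hits with e-value <= *max_evalue*.

    Self-hits (query == subject) are dropped.  Malformed lines raise
    :class:`ParseError` naming the offending line number.
    """
    records: list[SimilarityRecord] = []
    n_self = n_cutoff = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            query_id, subject_id = parts[0], parts[1]
            try:
                evalue = float(parts[10])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unparseable e-value {parts[10]!r}"
                ) from None
            if evalue < 0:
                raise ParseError(f"{path}:{lineno}: negative e-value {evalue!r}")
            if query_id == subject_id:
                n_self += 1
                continue
            if evalue > max_evalue:
                n_cutoff += 1
                continue
            records.append(SimilarityRecord(query_id, subject_id, evalue))
    logger.info(
        "read_blast_tabular(%s): kept %d, dropped %d self-hits, %d above e-value %g",
        path, len(records), n_self, n_cutoff, max_evalue,
    )
    return records


def read_operon_table(path: str | Path) -> list[OperonPairRecord]:
    """Read the operon pair TSV; unordered duplicate pairs keep the max probability."""
    best: dict[tuple[str, str, str], float] = {}
    order: list[tuple[str, str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["genome_id", "gene_a", "gene_b", "probability"]
        if header != expected:
            raise ParseError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            genome_id, gene_a, gene_b = parts[0], parts[1], parts[2]
            try:
                prob = float(parts[3])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unparseable probability {parts[3]!r}"
                ) from None
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: probability {prob!r} outside [0, 1]"
                )
            if gene_a == gene_b:
                raise ValidationError(f"{path}:{lineno}: self-pair {gene_a!r}")
            a, b = sorted((gene_a, gene_b))
            key = (genome_id, a, b)
            if key not in best:
                order.append(key)
                best[key] = prob
            else:
                best[key] = max(best[key], prob)
    return [
        OperonPairRecord(genome_id, a, b, best[(genome_id, a, b)])
        for genome_id, a, b in order
    ]


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read the gene catalog TSV (genome_id, gene_id, locus_index)."""
    rows: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["genome_id", "gene_id", "locus_index"]
        if header != expected:
            raise ParseError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            genome_id, gene_id = parts[0], parts[1]
            try:
                locus = int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unparseable locus index {parts[2]!r}"
                ) from None
            if locus < 0:
                raise ValidationError(f"{path}:{lineno}: negative locus index {locus}")
            rows.setdefault(genome_id, []).append((locus, gene_id))
    genomes: dict[str, list[str]] = {}
    for genome_id, entries in rows.items():
        entries.sort()
        loci = [e[0] for e in entries]
        if len(set(loci)) != len(loci):
            raise ValidationError(f"duplicate locus index in genome {genome_id!r}")
        genomes[genome_id] = [e[1] for e in entries]
    return GeneCatalog(genomes)


def read_annotation_groups(path: str | Path) -> AnnotationSet:
    """Read headerless two-column TSV (group_id, gene_id)."""
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            groups.setdefault(parts[0], set()).add(parts[1])
    annot = AnnotationSet(groups)
    for gid, members in annot.unusable_groups().items():
        logger.info("annotation group %s has %d gene(s): unusable for validation",
                    gid, len(members))
    return annot


# ---------------------------------------------------------------------------
# writers


def write_gene_catalog(path: str | Path, catalog: GeneCatalog) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_id\tlocus_index\n")
        for genome_id in catalog.genomes:
            for locus, gene_id in enumerate(catalog.genomes[genome_id]):
                fh.write(f"{genome_id}\t{gene_id}\t{locus}\n")


def write_operon_table(path: str | Path, records: Iterable[OperonPairRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_a\tgene_b\tprobability\n")
        for r in records:
            fh.write(f"{r.genome_id}\t{r.gene_a}\t{r.gene_b}\t{r.probability!r}\n")


def write_blast_tabular(path: str | Path, records: Iterable[SimilarityRecord]) -> None:
    """Write similarity records in minimal 12-column outfmt-6 shape.

    Columns other than query, subject and e-value carry placeholder values;
    they are ignored on read.
    """
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t0.0\t0\t0\t0\t0\t0\t0\t0\t{r.evalue!r}\t0.0\n"
            )


def write_annotation_groups(path: str | Path, annot: AnnotationSet) -> None:
    with open(path, "w") as fh:
        for group_id in sorted(annot.groups):
            for gene_id in sorted(annot.groups[group_id]):
                fh.write(f"{group_id}\t{gene_id}\n")


def write_edge_list(path: str | Path, network) -> None:
    """Serialize a functional network's edges; bit-exact round-trip via repr."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\tkind\n")
        for u, v, data in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in network.edges(data=True)),
            key=lambda t: (t[0], t[1]),
        ):
            fh.write(f"{u}\t{v}\t{data['weight']!r}\t{data['kind']}\n")


def read_edge_list(path: str | Path, catalog: GeneCatalog | None = None):
    """Read an edge-list TSV back into a functional network.

    If *catalog* is given, nodes carry genome/locus attributes and isolated
    catalog genes are included; edge endpoints absent from the catalog raise
    :class:`ValidationError`.
    """
    import networkx as nx

    graph = nx.Graph()
    if catalog is not None:
        for genome_id, genes in catalog.genomes.items():
            for locus, g in enumerate(genes):
                graph.add_node(g, genome=genome_id, locus=locus)
    offenders = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_a", "gene_b", "weight", "kind"]
        if header != expected:
            raise ParseError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            u, v, kind = parts[0], parts[1], parts[3]
            try:
                weight = float(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: unparseable weight {parts[2]!r}"
                ) from None
            if kind not in ("similarity", "operon"):
                raise ParseError(f"{path}:{lineno}: unknown edge kind {kind!r}")
            if catalog is not None:
                for g in (u, v):
                    if g not in catalog:
                        offenders.append(g)
            graph.add_edge(u, v, weight=weight, kind=kind)
    if offenders:
        raise ValidationError(
            f"{path}: edge genes absent from catalog: {sorted(set(offenders))}"
        )
    return graph


def write_ranking(path: str | Path, result) -> None:
    """Write a :class:`~genelink.distance.RankingResult` as a ranking TSV."""
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tdistance\tn_path_edges\n")
        for rank, (gene_id, dist, n_edges) in enumerate(result.iter_rows(), start=1):
            dist_s = INFINITY_TOKEN if math.isinf(dist) else repr(dist)
            n_s = "" if n_edges is None else str(n_edges)
            fh.write(f"{rank}\t{gene_id}\t{dist_s}\t{n_s}\n")


# ---------------------------------------------------------------------------
# cross-file validation


def check_gene_references(
    catalog: GeneCatalog,
    operons: Iterable[OperonPairRecord] = (),
    annotations: AnnotationSet | None = None,
) -> None:
    """Raise :class:`ValidationError` listing genes referenced but not catalogued."""
    offenders: set[str] = set()
    for r in operons:
        for g in (r.gene_a, r.gene_b):
            if g not in catalog:
                offenders.add(g)
            elif catalog.genome_of(g) != r.genome_id:
                raise ValidationError(
                    f"operon record assigns {g!r} to {r.genome_id!r} "
                    f"but catalog places it in {catalog.genome_of(g)!r}"
                )
    if annotations is not None:
        for members in annotations.groups.values():
            offenders.update(g for g in members if g not in catalog)
    if offenders:
        raise ValidationError(
            f"genes referenced but absent from catalog: {sorted(offenders)}"
        )
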