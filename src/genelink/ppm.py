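"""Phylogenetic-profile baseline (PPM).

Each gene's profile is a binary presence/absence vector over all genomes in
the catalog: 1 in its home genome and in every genome holding a similarity
hit at or below the presence e-value threshold.  Profile distance is
1 - Pearson correlation (the phi coefficient on binary vectors), so genes
that co-occur across genomes score close.  Rankings share the tie policy of
the network method so both can run through the same validation harness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .distance import RankingResult, TIE_POLICY
from .io import AnnotationSet, GeneCatalog, SimilarityRecord, ValidationError
from .validation import ValidationRun, leave_one_out_scored

#: default best-hit e-value for calling a gene present in a genome
DEFAULT_PRESENCE_EVALUE = 1e-5


@dataclass
class ProfileMatrix:
    """Genes x genomes binary presence matrix."""

    genes: list[str]
    genomes: list[str]
    matrix: np.ndarray  # shape (n_genes, n_genomes), entries in {0, 1}
    presence_evalue: float

    def __post_init__(self) -> None:
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.matrix[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(self.genomes) + "\n")
            for g in self.genes:
                row = self.row(g)
                fh.write(g + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def build_profiles(
    catalog: GeneCatalog,
    sims: Iterable[SimilarityRecord],
    presence_evalue: float = DEFAULT_PRESENCE_EVALUE,
) -> ProfileMatrix:
    """Call presence/absence of every catalog gene across all genomes.

    A gene is present in its home genome and in any genome containing a hit
    (either BLAST direction) with e-value <= *presence_evalue*.
    """
    genomes = list(catalog.genomes)
    genome_index = {g: i for i, g in enumerate(genomes)}
    genes = catalog.all_genes()
    gene_index = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(genomes)), dtype=np.uint8)
    for g in genes:
        mat[gene_index[g], genome_index[catalog.genome_of(g)]] = 1
    for r in sims:
        if r.evalue > presence_evalue:
            continue
        for g, other in ((r.query_id, r.subject_id), (r.subject_id, r.query_id)):
            if g not in catalog or other not in catalog:
                raise ValidationError(
                    f"similarity record names uncatalogued gene: {r.query_id!r}/{r.subject_id!r}"
                )
            mat[gene_index[g], genome_index[catalog.genome_of(other)]] = 1
    return ProfileMatrix(genes, genomes, mat, presence_evalue)


def profile_distance(row_a: Sequence[int], row_b: Sequence[int]) -> float:
    """1 - Pearson correlation of two equal-length binary vectors, in [0, 2].

    Zero-variance rows have no defined correlation; it is taken as 0, so a
    constant profile sits at distance 1 from everything.
    """
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(da @ da)
    nb = np.sqrt(db @ db)
    if na == 0.0 or nb == 0.0:
        return 1.0
    r = float((da @ db) / (na * nb))
    return 1.0 - min(1.0, max(-1.0, r))


def _mean_distance_to_seeds(
    matrix: ProfileMatrix, seeds: Sequence[str], candidate: str
) -> float:
    row = matrix.row(candidate)
    return float(np.mean([profile_distance(matrix.row(s), row) for s in seeds]))


def rank_by_profile(
    matrix: ProfileMatrix,
    seeds: Iterable[str],
    target_genome: str,
    catalog: GeneCatalog,
    exclude: Iterable[str] = (),
) -> RankingResult:
    """Rank genes of *target_genome* by mean profile distance to the seed rows
    (ascending; lexicographic tie-break, matching the network ranking)."""
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("empty seed set")
    if target_genome not in catalog.genomes:
        raise KeyError(f"unknown genome {target_genome!r}")
    skip = set(seeds) | set(exclude)
    candidates = [g for g in catalog.genomes[target_genome] if g not in skip]
    scored = [(g, _mean_distance_to_seeds(matrix, seeds, g)) for g in candidates]
    scored.sort(key=lambda t: (t[1], t[0]))
    return RankingResult(frozenset(seeds), target_genome, scored, TIE_POLICY)


def leave_one_out_profiles(
    matrix: ProfileMatrix,
    groups: AnnotationSet,
    mode: str,
    catalog: GeneCatalog,
    n_random: int = 99,
    rng_seed: int = 0,
) -> list[ValidationRun]:
    """Leave-one-out sweep for the profile baseline through the shared
    validation harness.  Profiles are built from raw similarity only, so no
    masking step is needed: group membership never enters a profile."""

    def scorer(seeds: Sequence[str], candidates: Sequence[str]) -> dict[str, float]:
        return {c: _mean_distance_to_seeds(matrix, seeds, c) for c in candidates}

    return leave_one_out_scored(scorer, groups, mode, catalog, n_random, rng_seed)
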