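"""Download-free synthetic corpora with the statistical structure the
network method exploits.

The generator emulates only the summary layer the pipeline consumes — gene
families with log-uniform within-family BLAST e-values, per-genome operon
structures with adjacent-pair probabilities, and sparse spurious background
hits near the e-value inclusion cutoff — not sequence evolution itself.

Planted ground-truth groups come in two flavors, all anchored in a
designated query genome:

* **co-occurrence groups**: three families sharing one presence pattern
  across genomes and sitting adjacent (one operon run) in every shared
  genome — the classic conserved-operon signal, detectable by profile
  correlation and by the network method alike.
* **bridge groups**: three families with independent presence patterns and
  *no* cross-family similarity, whose members are scattered (non-adjacent)
  in the query genome but sit together in one operon in a single
  third-party bridge genome.  Only a shortest path through that operon
  links them, so profile correlation is nearly blind to them.

Background operon runs are formed only over stretches of unplanted genes;
planted genes act as run breakers, which keeps bridge groups linked
exclusively through their bridge operon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as gio
from .io import (
    AnnotationSet,
    GeneCatalog,
    OperonPairRecord,
    SimilarityRecord,
)

BRIDGE = "bridge"
COOCCURRENCE = "cooccurrence"

PRESETS = ("mixed", "bridge-only", "cooccurrence-only")


class ConfigError(ValueError):
    """The corpus configuration cannot be realized."""


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of one synthetic corpus.

    Defaults give the standard benchmark corpus: 20 genomes of 100 genes,
    30 gene families all consumed by 10 planted groups of 3.
    """

    n_genomes: int = 20
    genes_per_genome: int = 100
    n_families: int = 30
    within_family_log10_evalue_range: tuple[float, float] = (-150.0, -30.0)
    background_hit_rate: float = 5e-5
    background_log10_evalue_range: tuple[float, float] = (-6.0, -3.0)
    operon_pair_probability_range: tuple[float, float] = (0.7, 0.99)
    inter_operon_probability_range: tuple[float, float] = (0.0, 0.2)
    n_planted_groups: int = 10
    group_size: int = 3
    bridge_fraction: float = 0.5
    family_presence_probability: float = 0.3
    cooccurrence_presence_probability: float = 0.4
    rng_seed: int = 7

    def __post_init__(self) -> None:
        for lo, hi in (
            self.within_family_log10_evalue_range,
            self.background_log10_evalue_range,
            self.operon_pair_probability_range,
            self.inter_operon_probability_range,
        ):
            if lo > hi:
                raise ConfigError(f"ill-ordered range ({lo}, {hi})")
        for lo, hi in (
            self.operon_pair_probability_range,
            self.inter_operon_probability_range,
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError("operon probability range outside [0, 1]")
        if not 0.0 <= self.bridge_fraction <= 1.0:
            raise ConfigError("bridge_fraction outside [0, 1]")
        if not 0.0 <= self.background_hit_rate <= 1.0:
            raise ConfigError("background_hit_rate outside [0, 1]")
        if min(self.n_genomes, self.genes_per_genome, self.n_families) < 1:
            raise ConfigError("corpus dimensions must be positive")
        if self.n_planted_groups * self.group_size > self.n_families:
            raise ConfigError(
                f"{self.n_planted_groups} groups x {self.group_size} families "
                f"exceed n_families={self.n_families}"
            )
        if self.n_genomes < 4:
            raise ConfigError("need at least 4 genomes (query, bridge, two others)")


@dataclass
class Corpus:
    catalog: GeneCatalog
    similarities: list[SimilarityRecord]
    operons: list[OperonPairRecord]
    groups: AnnotationSet
    group_kinds: dict[str, str]
    query_genome: str
    config: CorpusConfig


def preset(name: str) -> CorpusConfig:
    """Named benchmark configurations sharing one corpus geometry."""
    fractions = {"mixed": 0.5, "bridge-only": 1.0, "cooccurrence-only": 0.0}
    if name not in fractions:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESETS}")
    return CorpusConfig(bridge_fraction=fractions[name])


# a placement slot: (family_index or None, group_id or None, in_planted_run)
_Slot = tuple[int | None, str | None, bool]
_BACKGROUND: _Slot = (None, None, False)


def generate_corpus(config: CorpusConfig) -> Corpus:
    """Generate catalog, similarity and operon records, and ground truth.

    Deterministic given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_g = config.n_genomes
    genome_ids = [f"G{i:02d}" for i in range(n_g)]
    query = genome_ids[0]

    n_groups = config.n_planted_groups
    n_bridge = int(round(config.bridge_fraction * n_groups))
    group_ids = []
    group_kind: dict[str, str] = {}
    group_families: dict[str, list[int]] = {}
    fam = 0
    for gi in range(n_groups):
        kind = BRIDGE if gi < n_bridge else COOCCURRENCE
        gid = f"{kind}_{gi:02d}"
        group_ids.append(gid)
        group_kind[gid] = kind
        group_families[gid] = list(range(fam, fam + config.group_size))
        fam += config.group_size
    free_families = list(range(fam, config.n_families))
    family_group: dict[int, str] = {
        f: gid for gid, fams in group_families.items() for f in fams
    }

    # blocks[genome] is a list of runs of slots; multi-slot runs are operons
    blocks: dict[str, list[list[_Slot]]] = {g: [] for g in genome_ids}

    def other_genomes(p: float, forced: list[str]) -> list[str]:
        chosen = [g for g in genome_ids[1:] if rng.random() < p]
        for f in forced:
            if f not in chosen:
                chosen.append(f)
        while len(chosen) < 2:  # every family exists somewhere beyond the query
            extra = genome_ids[1 + rng.integers(0, n_g - 1)]
            if extra not in chosen:
                chosen.append(extra)
        return sorted(chosen, key=genome_ids.index)

    for gid in group_ids:
        fams = group_families[gid]
        if group_kind[gid] == BRIDGE:
            bridge_genome = genome_ids[1 + rng.integers(0, n_g - 1)]
            blocks[bridge_genome].append(
                [(f, gid, True) for f in fams]
            )
            for f in fams:
                homes = other_genomes(
                    config.family_presence_probability, [bridge_genome]
                )
                blocks[query].append([(f, gid, False)])
                for g in homes:
                    if g != bridge_genome:
                        blocks[g].append([(f, gid, False)])
        else:
            homes = other_genomes(config.cooccurrence_presence_probability, [])
            for g in [query] + homes:
                blocks[g].append([(f, gid, True) for f in fams])

    for f in free_families:
        homes = other_genomes(config.family_presence_probability, [])
        for g in [query] + homes:
            blocks[g].append([(f, None, False)])

    # fill with background singletons, shuffle block order, flatten
    layout: dict[str, list[_Slot]] = {}
    for g in genome_ids:
        used = sum(len(b) for b in blocks[g])
        if used > config.genes_per_genome:
            raise ConfigError(
                f"genome {g}: {used} planted genes exceed capacity "
                f"{config.genes_per_genome}; fewer/smaller families needed"
            )
        all_blocks = blocks[g] + [[_BACKGROUND]] * (config.genes_per_genome - used)
        order = rng.permutation(len(all_blocks))
        layout[g] = [slot for i in order for slot in all_blocks[i]]
        _separate_scattered_group_members(layout[g], rng)

    # gene ids by final locus; family membership and catalog
    catalog_map: dict[str, list[str]] = {}
    slot_of: dict[str, _Slot] = {}
    family_members: dict[int, list[str]] = {f: [] for f in range(config.n_families)}
    for g in genome_ids:
        genes = []
        for locus, slot in enumerate(layout[g]):
            gene_id = f"{g}_{locus:03d}"
            genes.append(gene_id)
            slot_of[gene_id] = slot
            if slot[0] is not None:
                family_members[slot[0]].append(gene_id)
        catalog_map[g] = genes
    catalog = GeneCatalog(catalog_map)

    # within-family similarity: log-uniform e-values, all member pairs
    lo_e, hi_e = config.within_family_log10_evalue_range
    sims: list[SimilarityRecord] = []
    for f in range(config.n_families):
        members = family_members[f]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                e = 10.0 ** rng.uniform(lo_e, hi_e)
                sims.append(SimilarityRecord(members[i], members[j], e))

    # spurious background hits near the inclusion cutoff; never within a
    # family or between families of one planted group
    all_genes = catalog.all_genes()
    n_total = len(all_genes)
    n_pairs = n_total * (n_total - 1) // 2
    n_background = int(rng.binomial(n_pairs, config.background_hit_rate))
    lo_b, hi_b = config.background_log10_evalue_range
    seen: set[tuple[str, str]] = set()
    for _ in range(n_background):
        i, j = rng.integers(0, n_total, size=2)
        if i == j:
            continue
        a, b = all_genes[i], all_genes[j]
        fa, ga, _ = slot_of[a]
        fb, gb, _ = slot_of[b]
        if fa is not None and fa == fb:
            continue
        if ga is not None and ga == gb:
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        sims.append(SimilarityRecord(key[0], key[1], 10.0 ** rng.uniform(lo_b, hi_b)))

    # operons: a probability for EVERY adjacent pair, the way a probabilistic
    # operon predictor reports.  Pairs inside one operon run (planted runs,
    # plus background genes chopped into random runs) draw from the in-operon
    # range; pairs spanning a run boundary draw from the low inter-operon
    # range, giving each chromosome a weakly connected backbone.
    p_lo, p_hi = config.operon_pair_probability_range
    q_lo, q_hi = config.inter_operon_probability_range
    operons: list[OperonPairRecord] = []
    for g in genome_ids:
        genes = catalog_map[g]
        slots = layout[g]
        # run id per locus: planted runs share a group-tag id, background
        # stretches are chopped into random-length runs, scattered planted
        # singletons are their own run
        run_id = [0] * len(slots)
        next_id = 0
        idx = 0
        while idx < len(slots):
            slot = slots[idx]
            if slot[2]:  # planted operon run: consume the whole block
                next_id += 1
                while idx < len(slots) and slots[idx][2] and slots[idx][1] == slot[1]:
                    run_id[idx] = next_id
                    idx += 1
            elif slot == _BACKGROUND:
                length = int(rng.choice([1, 2, 3, 4], p=[0.5, 0.25, 0.15, 0.10]))
                next_id += 1
                taken = 0
                while idx < len(slots) and slots[idx] == _BACKGROUND and taken < length:
                    run_id[idx] = next_id
                    idx += 1
                    taken += 1
            else:  # scattered family member: singleton run
                next_id += 1
                run_id[idx] = next_id
                idx += 1
        for i in range(len(slots) - 1):
            if run_id[i] == run_id[i + 1]:
                prob = float(rng.uniform(p_lo, p_hi))
            else:
                prob = float(rng.uniform(q_lo, q_hi))
            operons.append(OperonPairRecord(g, genes[i], genes[i + 1], prob))

    groups = AnnotationSet(
        {
            gid: {
                m
                for f in group_families[gid]
                for m in family_members[f]
                if catalog.genome_of(m) == query
            }
            for gid in group_ids
        }
    )
    return Corpus(catalog, sims, operons, groups, group_kind, query, config)


def _separate_scattered_group_members(slots: list[_Slot], rng: np.random.Generator) -> None:
    """Break up adjacent scattered (non-run) members of one group by swapping
    one of them with a background gene elsewhere in the genome."""
    for _ in range(10 * len(slots)):
        bad = None
        for i in range(len(slots) - 1):
            a, b = slots[i], slots[i + 1]
            if (
                a[1] is not None
                and a[1] == b[1]
                and not a[2]
                and not b[2]
            ):
                bad = i + 1
                break
        if bad is None:
            return
        bg = [k for k, s in enumerate(slots) if s == _BACKGROUND]
        if not bg:
            raise ConfigError("cannot separate planted genes: no background slots")
        j = int(rng.choice(bg))
        slots[bad], slots[j] = slots[j], slots[bad]
    raise ConfigError("could not separate scattered group members")


def corpus_to_files(corpus: Corpus, directory: str | Path) -> dict[str, Path]:
    """Write the four pipeline inputs plus ground truth; byte-identical when
    regenerated from the same config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": directory / "catalog.tsv",
        "similarity": directory / "similarity.blast.tsv",
        "operons": directory / "operons.tsv",
        "groups": directory / "groups.tsv",
        "ground_truth": directory / "ground_truth.json",
    }
    gio.write_gene_catalog(paths["catalog"], corpus.catalog)
    gio.write_blast_tabular(paths["similarity"], corpus.similarities)
    gio.write_operon_table(paths["operons"], corpus.operons)
    gio.write_annotation_groups(paths["groups"], corpus.groups)
    truth = {
        "query_genome": corpus.query_genome,
        "rng_seed": corpus.config.rng_seed,
        "groups": {
            gid: {
                "kind": corpus.group_kinds[gid],
                "members": sorted(corpus.groups.groups[gid]),
            }
            for gid in sorted(corpus.groups.groups)
        },
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
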