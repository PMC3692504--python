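import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

import genelink.io as gio
from genelink import (
    CorpusConfig,
    build_network,
    corpus_to_files,
    generate_corpus,
    leave_one_out,
    preset,
    roc_auc,
)
from genelink.synthetic import BRIDGE, COOCCURRENCE, ConfigError


def _hash_dir(d: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
    }


class TestConfig:
    def test_infeasible_family_count(self):
        with pytest.raises(ConfigError, match="exceed"):
            CorpusConfig(n_families=5, n_planted_groups=4, group_size=3)

    def test_overfull_genome_rejected(self):
        cfg = CorpusConfig(
            n_genomes=4, genes_per_genome=5, n_families=30, n_planted_groups=10
        )
        with pytest.raises(ConfigError, match="capacity"):
            generate_corpus(cfg)

    def test_ill_ordered_range(self):
        with pytest.raises(ConfigError):
            CorpusConfig(within_family_log10_evalue_range=(-10.0, -50.0))

    @pytest.mark.parametrize(
        "name,fraction", [("mixed", 0.5), ("bridge-only", 1.0), ("cooccurrence-only", 0.0)]
    )
    def test_presets(self, name, fraction):
        assert preset(name).bridge_fraction == fraction

    def test_unknown_preset(self):
        with pytest.raises(ConfigError):
            preset("nope")


class TestGroundTruth:
    def test_flavor_counts_follow_bridge_fraction(self, small_corpus):
        kinds = list(small_corpus.group_kinds.values())
        assert kinds.count(BRIDGE) == 2 and kinds.count(COOCCURRENCE) == 2

    def test_bridge_fraction_zero_all_cooccurrence(self):
        cfg = dataclasses.replace(preset("cooccurrence-only"), rng_seed=3)
        corpus = generate_corpus(cfg)
        assert set(corpus.group_kinds.values()) == {COOCCURRENCE}

    def test_no_planted_groups_gives_empty_annotation(self):
        cfg = CorpusConfig(n_planted_groups=0)
        assert generate_corpus(cfg).groups.groups == {}

    def test_groups_never_share_genes(self, small_corpus):
        seen = set()
        for members in small_corpus.groups.groups.values():
            assert not (members & seen)
            seen |= members

    def test_groups_are_usable_and_in_query_genome(self, small_corpus):
        for members in small_corpus.groups.groups.values():
            assert len(members) >= 3
            for g in members:
                assert small_corpus.catalog.genome_of(g) == small_corpus.query_genome

    def test_bridge_groups_have_no_cross_family_similarity(self):
        corpus = generate_corpus(preset("bridge-only"))
        group_of = {}
        for gid, members in corpus.groups.groups.items():
            for m in members:
                group_of[m] = gid
        # scan every similarity record: genes of one bridge group never hit
        # each other directly (their families are mutually dissimilar)
        for rec in corpus.similarities:
            ga, gb = group_of.get(rec.query_id), group_of.get(rec.subject_id)
            assert ga is None or gb is None or ga != gb

    def test_operon_probabilities_cover_every_adjacent_pair(self, small_corpus):
        pairs = {
            (r.genome_id, r.gene_a, r.gene_b) for r in small_corpus.operons
        }
        for genome, genes in small_corpus.catalog.genomes.items():
            for a, b in zip(genes, genes[1:]):
                lo, hi = sorted((a, b))
                assert (genome, lo, hi) in pairs


class TestFileEmission:
    def test_same_seed_reproduces_identical_files(self, tmp_path):
        cfg = CorpusConfig(n_genomes=6, genes_per_genome=30, n_families=9,
                           n_planted_groups=3, rng_seed=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        corpus_to_files(generate_corpus(cfg), d1)
        corpus_to_files(generate_corpus(cfg), d2)
        assert _hash_dir(d1) == _hash_dir(d2)

    def test_changed_seed_changes_similarity_file(self, tmp_path):
        base = CorpusConfig(n_genomes=6, genes_per_genome=30, n_families=9,
                            n_planted_groups=3, rng_seed=2)
        other = dataclasses.replace(base, rng_seed=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        corpus_to_files(generate_corpus(base), d1)
        corpus_to_files(generate_corpus(other), d2)
        assert (
            _hash_dir(d1)["similarity.blast.tsv"]
            != _hash_dir(d2)["similarity.blast.tsv"]
        )

    def test_round_trip_through_readers(self, tmp_path, small_corpus):
        paths = corpus_to_files(small_corpus, tmp_path)
        catalog = gio.read_gene_catalog(paths["catalog"])
        assert catalog.genomes == small_corpus.catalog.genomes
        sims = gio.read_blast_tabular(paths["similarity"], max_evalue=float("inf"))
        orig = {
            (min(r.query_id, r.subject_id), max(r.query_id, r.subject_id), r.evalue)
            for r in small_corpus.similarities
        }
        got = {
            (min(r.query_id, r.subject_id), max(r.query_id, r.subject_id), r.evalue)
            for r in sims
        }
        assert got == orig
        ops = gio.read_operon_table(paths["operons"])
        assert {dataclasses.astuple(r) for r in ops} == {
            dataclasses.astuple(
                gio.OperonPairRecord(r.genome_id, *sorted((r.gene_a, r.gene_b)),
                                     r.probability)
            )
            for r in small_corpus.operons
        }
        groups = gio.read_annotation_groups(paths["groups"])
        assert groups.groups == small_corpus.groups.groups
        truth = json.loads(paths["ground_truth"].read_text())
        assert truth["query_genome"] == small_corpus.query_genome


class TestPlantedSignal:
    def test_bridge_partners_recovered_at_rank_one_in_majority(self):
        corpus = generate_corpus(preset("mixed"))
        net = build_network(corpus.catalog, corpus.similarities, corpus.operons)
        bridge_ids = {
            gid for gid, k in corpus.group_kinds.items() if k == BRIDGE
        }
        groups = gio.AnnotationSet(
            {gid: corpus.groups.groups[gid] for gid in bridge_ids}
        )
        runs = leave_one_out(net, groups, "random_control", corpus.catalog, rng_seed=1)
        rank_one = sum(r.positive_rank == 1 and r.n_ties_at_rank == 0 for r in runs)
        assert rank_one > len(runs) / 2

    def test_background_noise_monotonically_degrades_auc(self):
        # more spurious near-cutoff hits -> weaker mean signal, at three
        # noise rates averaged over five generator seeds
        mean_aucs = []
        for rate in (1e-4, 1e-3, 1e-2):
            aucs = []
            for seed in range(5):
                cfg = dataclasses.replace(
                    preset("mixed"), background_hit_rate=rate, rng_seed=100 + seed
                )
                corpus = generate_corpus(cfg)
                net = build_network(
                    corpus.catalog, corpus.similarities, corpus.operons
                )
                runs = leave_one_out(
                    net, corpus.groups, "random_control", corpus.catalog,
                    rng_seed=seed,
                )
                aucs.append(roc_auc(runs)[1])
            mean_aucs.append(float(np.mean(aucs)))
        assert mean_aucs[0] > mean_aucs[1] > mean_aucs[2]
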