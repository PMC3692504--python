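import json
import math

import networkx as nx
import numpy as np
import pytest

from genelink import (
    AnnotationSet,
    GeneCatalog,
    ValidationReport,
    ValidationRun,
    benchmark,
    build_network,
    leave_one_out,
    network_hash,
    roc_auc,
    top_precision,
)
from genelink.validation import (
    RANDOM_CONTROL,
    WHOLE_GENOME,
    leave_one_out_scored,
    make_report,
    trapezoid_auc,
)


def bridge_corpus():
    """Query genome Q holds group {A, B, C} plus controls; the three genes
    are linked only through an operon run Ap-Bp-Cp in genome T."""
    catalog = GeneCatalog(
        {"Q": ["A", "c1", "B", "c2", "C"], "T": ["Ap", "Bp", "Cp"]}
    )
    g = nx.Graph()
    for genome, genes in catalog.genomes.items():
        for locus, gene in enumerate(genes):
            g.add_node(gene, genome=genome, locus=locus)
    g.add_edge("A", "Ap", weight=0.3, kind="similarity")
    g.add_edge("Ap", "Bp", weight=0.05, kind="operon")
    g.add_edge("Bp", "B", weight=0.4, kind="similarity")
    g.add_edge("Bp", "Cp", weight=0.05, kind="operon")
    g.add_edge("Cp", "C", weight=0.35, kind="similarity")
    groups = AnnotationSet({"grp": {"A", "B", "C"}})
    return catalog, g, groups


class TestProtocol:
    def test_each_member_serves_as_positive_with_rest_as_seeds(self, tiny_catalog):
        seen = {}

        def scorer(seeds, candidates):
            positive = candidates[0]
            seen[positive] = set(seeds)
            return {c: 1.0 for c in candidates}

        groups = AnnotationSet({"g": {"a1", "a2", "a3"}})
        runs = leave_one_out_scored(
            scorer, groups, WHOLE_GENOME, tiny_catalog, rng_seed=0
        )
        assert len(runs) == 3
        assert seen == {
            "a1": {"a2", "a3"},
            "a2": {"a1", "a3"},
            "a3": {"a1", "a2"},
        }

    def test_small_groups_skipped(self, tiny_catalog):
        groups = AnnotationSet({"small": {"a1", "a2"}})
        runs = leave_one_out_scored(
            lambda s, c: {x: 0.0 for x in c}, groups, WHOLE_GENOME, tiny_catalog
        )
        assert runs == []

    def test_network_restored_bit_exactly(self):
        catalog, net, groups = bridge_corpus()
        net.add_edge("A", "B", weight=0.01, kind="operon")  # direct pos-seed edge
        before = network_hash(net)
        leave_one_out(net, groups, WHOLE_GENOME, catalog, rng_seed=0)
        assert network_hash(net) == before

    def test_bridge_survives_masking_and_positive_ranks_first(self):
        catalog, net, groups = bridge_corpus()
        # direct positive-seed edges exist and must be masked away ...
        net.add_edge("A", "B", weight=0.01, kind="operon")
        runs = leave_one_out(net, groups, WHOLE_GENOME, catalog, rng_seed=0)
        # ... yet every positive stays linked to the seeds via the T operon
        assert [r.positive_rank for r in runs] == [1, 1, 1]
        assert [r.n_ties_at_rank for r in runs] == [0, 0, 0]
        assert all(r.n_controls == 2 for r in runs)  # c1, c2 only

    def test_random_controls_exclude_group_and_cap(self):
        catalog, net, groups = bridge_corpus()
        runs = leave_one_out(
            net, groups, RANDOM_CONTROL, catalog, n_random=99, rng_seed=0
        )
        assert all(r.n_controls == 2 for r in runs)  # pool capped at |Q|-3


class TestTopPrecision:
    def test_paper_style_proportion(self):
        runs = [
            ValidationRun("g", f"p{i}", 100, 1 if i < 36 else 5, 0)
            for i in range(100)
        ]
        assert top_precision(runs) == pytest.approx(0.36)

    def test_all_rank_one_untied(self):
        runs = [ValidationRun("g", "p", 10, 1, 0)] * 5
        assert top_precision(runs) == 1.0

    def test_rank_one_requires_no_ties(self):
        # a tie at the top counts as failure (pessimistic ranking pushes
        # the tied positive past rank 1)
        runs = [ValidationRun("g", "p", 10, 2, 1)]
        assert top_precision(runs) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_precision([])

    def test_top_bounded_by_rank_cdf(self):
        rng = np.random.default_rng(4)
        runs = [
            ValidationRun("g", f"p{i}", 50, int(rng.integers(1, 52)), 0)
            for i in range(200)
        ]
        top = top_precision(runs)
        for k in (1, 2, 5, 10):
            frac = sum(r.positive_rank <= k for r in runs) / len(runs)
            assert top <= frac + 1e-12


class TestRocAuc:
    def test_perfect_ranker(self):
        runs = [ValidationRun("g", f"p{i}", 100, 1, 0) for i in range(20)]
        roc, auc = roc_auc(runs)
        assert auc == 1.0
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_single_midpoint_run(self):
        roc, auc = roc_auc([ValidationRun("g", "p", 100, 51, 0)])
        assert auc == pytest.approx(0.5)

    def test_inverted_ranker_scores_at_floor(self):
        runs = [ValidationRun("g", f"p{i}", 100, 101, 0) for i in range(10)]
        _, auc = roc_auc(runs)
        assert auc == 0.0

    def test_all_tied_gives_half(self):
        _, auc = roc_auc([ValidationRun("g", "p", 10, 11, 10)])
        assert auc == pytest.approx(0.5)

    def test_roc_monotone_and_anchored(self):
        rng = np.random.default_rng(12)
        runs = [
            ValidationRun("g", f"p{i}", 30, int(rng.integers(1, 32)), 0)
            for i in range(50)
        ]
        roc, _ = roc_auc(runs)
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)
        xs = [p[0] for p in roc]
        ys = [p[1] for p in roc]
        assert xs == sorted(xs) and ys == sorted(ys)

    def test_trapezoid_equals_mean_standing(self):
        rng = np.random.default_rng(8)
        runs = []
        for i in range(300):
            n = int(rng.integers(5, 120))
            ties = int(rng.integers(0, 4))
            closer = int(rng.integers(0, n - ties + 1))
            runs.append(ValidationRun("g", f"p{i}", n, 1 + closer + ties, ties))
        roc, auc = roc_auc(runs)
        assert abs(trapezoid_auc(roc) - auc) < 1e-9

    def test_uniform_random_ranks_converge_to_half(self):
        # 10,000 simulated runs with ranks uniform on [1, n+1]
        rng = np.random.default_rng(2024)
        runs = [
            ValidationRun("g", f"p{i}", 100, int(rng.integers(1, 102)), 0)
            for i in range(10_000)
        ]
        _, auc = roc_auc(runs)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_rank_invariant_enforced(self):
        with pytest.raises(ValueError):
            ValidationRun("g", "p", 10, 12, 0)


class TestBenchmark:
    def test_two_modes_and_report_round_trip(self, small_corpus):
        net = build_network(
            small_corpus.catalog, small_corpus.similarities, small_corpus.operons
        )
        reports = benchmark(
            net,
            small_corpus.groups,
            small_corpus.catalog,
            modes=(RANDOM_CONTROL, WHOLE_GENOME),
            n_random=20,
            rng_seed=5,
        )
        assert set(reports) == {RANDOM_CONTROL, WHOLE_GENOME}
        for rep in reports.values():
            assert 0.0 <= rep.auc <= 1.0
            assert rep.rng_seed == 5
            back = ValidationReport.from_json(rep.to_json())
            assert back.runs == rep.runs and back.auc == rep.auc
            assert back.roc == rep.roc

    def test_permuted_network_loses_signal(self, small_corpus):
        net = build_network(
            small_corpus.catalog, small_corpus.similarities, small_corpus.operons
        )
        reports = benchmark(
            net,
            small_corpus.groups,
            small_corpus.catalog,
            modes=(RANDOM_CONTROL,),
            n_random=30,
            rng_seed=3,
            include_permuted=True,
        )
        assert reports[RANDOM_CONTROL + "_permuted"].auc < reports[RANDOM_CONTROL].auc
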