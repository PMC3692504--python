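"""Leave-one-out cross-validation and the TOP / ROC / AUC metrics.

Protocol: within each functional group (an EC-number or pathway gene set
with at least three members) every member in turn serves as positive
control while the remaining members are seed genes.  The positive gene is
made "functionally unknown" by temporarily deleting all of its edges to the
seed genes; it is then prioritized by mean functional distance against
either 99 randomly selected genes of its genome (``random_control``) or all
remaining genes of its genome (``whole_genome``).  Top One Precision (TOP)
is the fraction of runs where the positive ranks first, and the ROC/AUC
summarize its standing against the controls across runs.

Rank convention: ``positive_rank`` counts tied controls as ranked ahead
(pessimistic competition ranking), so rank 1 implies an untied win; the AUC
gives tied controls the conventional half credit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .distance import _aggregate_from_maps, seed_distance_maps
from .io import AnnotationSet, GeneCatalog
from .network import permute_network

logger = logging.getLogger(__name__)

RANDOM_CONTROL = "random_control"
WHOLE_GENOME = "whole_genome"
MODES = (RANDOM_CONTROL, WHOLE_GENOME)

#: paper-style default number of random control genes per run
DEFAULT_N_RANDOM = 99

Scorer = Callable[[Sequence[str], Sequence[str]], Mapping[str, float]]


@dataclass(frozen=True)
class ValidationRun:
    """Outcome of one leave-one-out run."""

    group_id: str
    positive_gene: str
    n_controls: int
    positive_rank: int  # 1 + controls strictly closer + controls tied
    n_ties_at_rank: int

    def __post_init__(self) -> None:
        if not 1 <= self.positive_rank <= self.n_controls + 1:
            raise ValueError(
                f"rank {self.positive_rank} outside [1, {self.n_controls + 1}]"
            )

    @property
    def standing(self) -> float:
        """Fraction of controls the positive outranks (ties count half)."""
        return (
            self.n_controls - (self.positive_rank - 1) + 0.5 * self.n_ties_at_rank
        ) / self.n_controls


@dataclass
class ValidationReport:
    """Per-run ranks plus TOP and AUC summaries for one validation sweep."""

    runs: list[ValidationRun]
    top_precision: float
    auc: float
    roc: list[tuple[float, float]]
    config: dict
    rng_seed: int

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "rng_seed": self.rng_seed,
            "top_precision": self.top_precision,
            "auc": self.auc,
            "roc": [list(p) for p in self.roc],
            "runs": [dataclasses.asdict(r) for r in self.runs],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        d = json.loads(text)
        return cls(
            runs=[ValidationRun(**r) for r in d["runs"]],
            top_precision=d["top_precision"],
            auc=d["auc"],
            roc=[tuple(p) for p in d["roc"]],
            config=d["config"],
            rng_seed=d["rng_seed"],
        )


def _rank_against_controls(
    scores: Mapping[str, float], positive: str, controls: Sequence[str]
) -> tuple[int, int]:
    d_pos = scores[positive]
    closer = ties = 0
    for c in controls:
        d = scores[c]
        if d < d_pos:
            closer += 1
        elif d == d_pos or (math.isinf(d) and math.isinf(d_pos)):
            ties += 1
    return 1 + closer + ties, ties


def _select_controls(
    mode: str,
    positive: str,
    group: set[str],
    catalog: GeneCatalog,
    n_random: int,
    rng: np.random.Generator,
) -> list[str]:
    genome = catalog.genome_of(positive)
    pool = sorted(g for g in catalog.genomes[genome] if g not in group)
    if mode == WHOLE_GENOME:
        return pool
    if mode != RANDOM_CONTROL:
        raise ValueError(f"unknown validation mode {mode!r}")
    k = min(n_random, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def leave_one_out_scored(
    scorer: Scorer,
    groups: AnnotationSet,
    mode: str,
    catalog: GeneCatalog,
    n_random: int = DEFAULT_N_RANDOM,
    rng_seed: int = 0,
    prepare: Callable[[str, Sequence[str]], None] | None = None,
    restore: Callable[[], None] | None = None,
) -> list[ValidationRun]:
    """Generic leave-one-out sweep over any scorer.

    ``scorer(seeds, candidates)`` returns the distance of each candidate to
    the seed set.  ``prepare(positive, seeds)`` / ``restore()`` bracket each
    run (used by the network method to mask and restore positive-seed
    edges).  Deterministic given *rng_seed*.
    """
    rng = np.random.default_rng(rng_seed)
    runs: list[ValidationRun] = []
    capped = False
    for group_id in sorted(groups.groups):
        members = groups.groups[group_id]
        usable = sorted(g for g in members if g in catalog)
        if len(usable) < AnnotationSet.MIN_USABLE:
            logger.warning(
                "group %s has %d catalogued gene(s) (<%d): skipped",
                group_id, len(usable), AnnotationSet.MIN_USABLE,
            )
            continue
        for positive in usable:
            seeds = [g for g in usable if g != positive]
            controls = _select_controls(
                mode, positive, set(usable), catalog, n_random, rng
            )
            if mode == RANDOM_CONTROL and len(controls) < n_random:
                capped = True
            if prepare is not None:
                prepare(positive, seeds)
            try:
                scores = scorer(seeds, [positive] + controls)
            finally:
                if restore is not None:
                    restore()
            rank, ties = _rank_against_controls(scores, positive, controls)
            runs.append(ValidationRun(group_id, positive, len(controls), rank, ties))
    if capped:
        logger.warning(
            "random control pool smaller than n_random=%d in some runs; capped",
            n_random,
        )
    return runs


def leave_one_out(
    network: nx.Graph,
    groups: AnnotationSet,
    mode: str,
    catalog: GeneCatalog,
    n_random: int = DEFAULT_N_RANDOM,
    rng_seed: int = 0,
) -> list[ValidationRun]:
    """Network-method leave-one-out sweep with positive-seed edge masking.

    Only edges between the positive gene and the seed genes are deleted
    (seed-seed and positive-control edges are untouched); the network is
    restored bit-exactly after each run.
    """
    masked: list[tuple[str, str, dict]] = []

    def prepare(positive: str, seeds: Sequence[str]) -> None:
        for s in seeds:
            if network.has_edge(positive, s):
                masked.append((positive, s, dict(network[positive][s])))
                network.remove_edge(positive, s)

    def restore() -> None:
        while masked:
            u, v, data = masked.pop()
            network.add_edge(u, v, **data)

    def scorer(seeds: Sequence[str], candidates: Sequence[str]) -> dict[str, float]:
        maps = seed_distance_maps(network, seeds)
        return {c: _aggregate_from_maps(maps, c) for c in candidates}

    return leave_one_out_scored(
        scorer, groups, mode, catalog, n_random, rng_seed,
        prepare=prepare, restore=restore,
    )


def top_precision(runs: Sequence[ValidationRun]) -> float:
    """Fraction of runs where the positive ranks first, untied."""
    if not runs:
        raise ValueError("no validation runs")
    hits = sum(1 for r in runs if r.positive_rank == 1 and r.n_ties_at_rank == 0)
    return hits / len(runs)


def roc_auc(runs: Sequence[ValidationRun]) -> tuple[list[tuple[float, float]], float]:
    """Pooled ROC curve and AUC.

    The AUC is the mean standing of the positive against its controls (ties
    half credit).  The ROC sweeps a control-rank-fraction threshold theta:
    at theta, each run admits its top theta-fraction of controls
    (FPR = theta) and the positive is admitted once theta passes the
    controls ranked ahead of it, linearly across a tie block.  Vertical
    averaging of the per-run curves makes the trapezoidal area equal the
    mean standing.
    """
    if not runs:
        raise ValueError("no validation runs")
    auc = float(np.mean([r.standing for r in runs]))

    breaks = {0.0, 1.0}
    params = []  # (c/n, (c+t)/n) per run
    for r in runs:
        c = r.positive_rank - 1 - r.n_ties_at_rank
        lo = c / r.n_controls
        hi = (c + r.n_ties_at_rank) / r.n_controls
        params.append((lo, hi))
        breaks.add(lo)
        breaks.add(hi)
    thetas = sorted(breaks)

    def run_tpr(theta: float, lo: float, hi: float, closed: bool) -> float:
        if hi > lo:  # linear ramp across the tie block
            return min(1.0, max(0.0, (theta - lo) / (hi - lo)))
        if closed:  # step, right value
            return 1.0 if theta >= lo else 0.0
        return 1.0 if theta > lo else 0.0  # step, left limit

    # emit left limit and right value at each breakpoint so that untied
    # runs' steps become vertical segments and the trapezoid stays exact
    roc: list[tuple[float, float]] = []
    for theta in thetas:
        for closed in (False, True):
            tpr = float(np.mean([run_tpr(theta, lo, hi, closed) for lo, hi in params]))
            if not roc or roc[-1] != (theta, tpr):
                roc.append((theta, tpr))
    if roc[0] != (0.0, 0.0):
        roc.insert(0, (0.0, 0.0))
    return roc, auc


def trapezoid_auc(roc: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC polyline (independent of mean standing)."""
    xs = np.array([p[0] for p in roc])
    ys = np.array([p[1] for p in roc])
    return float(np.trapezoid(ys, xs))


def make_report(
    runs: list[ValidationRun], config: dict, rng_seed: int
) -> ValidationReport:
    roc, auc = roc_auc(runs)
    return ValidationReport(
        runs=runs,
        top_precision=top_precision(runs),
        auc=auc,
        roc=roc,
        config=config,
        rng_seed=rng_seed,
    )


def benchmark(
    network: nx.Graph,
    groups: AnnotationSet,
    catalog: GeneCatalog,
    modes: Sequence[str] = (RANDOM_CONTROL,),
    n_random: int = DEFAULT_N_RANDOM,
    rng_seed: int = 0,
    include_permuted: bool = False,
    swap_factor: int = 10,
) -> dict[str, ValidationReport]:
    """Run leave-one-out validation for each mode; optionally repeat on a
    degree-preserving permuted network as a topology control.  Returns a
    mapping from mode (plus ``<mode>_permuted``) to report; all reports
    share the rng provenance derived from *rng_seed*."""
    reports: dict[str, ValidationReport] = {}
    nets: list[tuple[str, nx.Graph]] = [("", network)]
    if include_permuted:
        nets.append(("_permuted", permute_network(network, rng_seed, swap_factor)))
    for suffix, net in nets:
        for mode in modes:
            config = {
                "mode": mode,
                "n_random": n_random,
                "permuted": bool(suffix),
                "swap_factor": swap_factor,
            }
            runs = leave_one_out(net, groups, mode, catalog, n_random, rng_seed)
            reports[mode + suffix] = make_report(runs, config, rng_seed)
    return reports
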