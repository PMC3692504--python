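# Methods

## Network model

Each catalogued gene is one node; undirected edges arise from two evidence
channels, both transformed onto a common [0, 1] scale where small weight
means strong linkage, so that path length is a meaningful composite of
heterogeneous evidence.

**Similarity edges.** For a gene pair with BLAST e-value `E` the weight is
`w_s = 1 + log10(max(E, 1e-185))/185`, clamped to [0, 1]. The 1e-185 floor
mirrors BLAST's own underflow behaviour (smaller e-values are printed as
0), which makes 185 the natural normalization constant: the transform maps
the whole representable e-value range onto [0, 1] and is strictly
decreasing in −log10(E) between the floor and E = 1. BLAST output is
asymmetric; we take the minimum e-value over both directions and the best
HSP per pair, since the network is undirected. E-values above the
inclusion cutoff (`max_evalue`, default 1e-3) contribute no edge: the
transform would place them in the topmost ~2 % of the weight range, where
they add noise paths but negligible signal. The cutoff is configuration,
not model.

**Operon edges.** For an adjacent same-genome pair with predictor
probability `P` of co-residing in an operon, `w_o = 1 − P`. Only
adjacent-pair probabilities are consumed; longer-range pairs within one
operon connect through the chain of adjacent edges.

**Merging.** A pair supported by both channels keeps the single smaller
weight, labelled with the winning evidence kind (similarity wins exact
ties, an arbitrary but fixed rule). For shortest-path queries this is
exactly equivalent to keeping parallel edges, because Dijkstra would never
traverse the larger of two parallel weights; merging simply keeps the
graph simple.

## Distances, ranking, explanation

Functional distance is the exact weighted shortest-path value (Dijkstra;
all weights are non-negative by construction). Seed sets aggregate by the
arithmetic mean of per-seed distances; a candidate unreachable from *any*
seed is assigned infinite aggregate distance. The alternative — averaging
only finite summands — would make candidates reachable from a single seed
indistinguishable from candidates reachable from all seeds; the absorbing
rule is the conservative choice and unreachable candidates always rank
last. Ranking sorts ascending with lexicographic tie-break on gene id
(recorded in `RankingResult.tie_policy`); determinism matters more than
any particular tie order. Path explanations re-run an in-package Dijkstra
with a smallest-id predecessor rule so the reported path is the unique
lexicographically favoured one among equals.

## Validation harness

Leave-one-out over annotation groups with ≥ 3 members (a positive needs at
least two seeds). Masking removes only positive↔seed edges — seed↔seed and
positive↔control edges stay — and the edge payloads are restored
bit-exactly after each run. Controls are drawn from the positive's own
genome excluding all group members: 99 random genes (capped with a warning
when the genome is smaller) or the whole remaining genome.

`positive_rank` uses pessimistic competition ranking: controls tied with
the positive count as ranked ahead. Under this convention rank 1 is an
untied win, TOP (`rank == 1`, no ties) is the strict reading of "ranked
highest", and the AUC standing
`s = (n − (rank − 1) + t/2)/n` (with `t` ties among `n` controls) equals
the Mann–Whitney statistic with half credit for ties. The pooled ROC
sweeps a control-rank-fraction threshold θ ∈ [0, 1]: each run admits its
top θ-fraction of controls (so FPR = θ exactly), the positive enters as a
step at its control quantile or as a linear ramp across a tie block, and
runs are averaged vertically. Steps are emitted as vertical segments, so
the trapezoidal area under the pooled curve equals the mean standing to
machine precision — the two AUC routes are required to agree to 1e-9 and
serve as mutual checks.

## Permutation control

`permute_network` applies `swap_factor × |E|` attempted double-edge swaps
(default factor 10): edges (u,v), (x,y) become (u,x), (v,y) unless a
self-loop or duplicate would result. Node set and degree sequence are
preserved exactly; each surviving edge carries the (weight, kind) payload
of one parent, so the weight distribution is preserved as a multiset. The
control answers: how much of the validation performance survives when
only degrees — not the arrangement of edges — are kept? Implemented
in-package because the payload contract and seeded determinism are part of
the specification of the operation.

## Phylogenetic-profile baseline

Profiles are binary presence vectors over all genomes: a gene is present
in its home genome and wherever it has a hit at e-value ≤ 1e-5 (a
conventional stringent homolog-calling threshold; the presence cutoff is
deliberately stricter than the network's edge-inclusion cutoff, since
presence calls tolerate no noise). Distance is 1 − Pearson correlation
(on binary vectors this is the phi coefficient); zero-variance rows get
correlation 0, i.e. distance 1 to everything. The home genome is included
in the vector. The baseline shares the ranking tie policy and the
leave-one-out harness; it needs no masking step because profiles are
computed from raw similarity only and never see group membership.

## Synthetic corpora

The generator emulates the *summary statistics* the pipeline consumes, not
sequence evolution. Defaults define the standard benchmark geometry: 20
genomes × 100 genes, 30 families, 10 planted groups of 3 genes anchored in
query genome `G00`, seed 7, presets `mixed` / `bridge-only` /
`cooccurrence-only` differing only in the bridge fraction (0.5 / 1.0 /
0.0).

- Within-family e-values are log-uniform on [1e-150, 1e-30] — deep into
  confident-homology territory with wide spread, the simplest distribution
  with the needed monotone structure. All member pairs receive a record.
- Background spurious hits occur at 5e-5 per gene pair (≈ 100 hits per
  corpus) with e-values log-uniform on [1e-6, 1e-3], i.e. hugging the
  inclusion cutoff: weak long edges that add noise paths, as real
  low-significance hits do. They never fall within one family or within
  one planted group.
- **Operon probabilities cover every adjacent pair**, the way a
  probabilistic operon predictor reports: pairs inside an operon run draw
  from U[0.70, 0.99], pairs spanning a run boundary from U[0.0, 0.2].
  Background genes are chopped into runs of length 1–4 (mean 1.85, ~73 %
  of background genes inside a multi-gene run, in line with typical
  prokaryotic operon coverage). The low-probability boundary pairs give
  each chromosome a weakly connected backbone — without it, a large
  fraction of genes would be isolated nodes, and the degree-preserving
  permutation control could be beaten on reachability alone, which no real
  prokaryotic gene network permits.
- **Bridge groups** (the operon-bridge motif): three mutually dissimilar
  families, each present in the query genome, one common third-party
  bridge genome, and otherwise independent genomes (presence probability
  0.3). In the bridge genome the three members sit in one operon run; in
  every other genome they are scattered, never adjacent. Zero cross-family
  similarity within the group is enforced and asserted by a scan. Only a
  path through the bridge operon connects the group.
- **Co-occurrence groups**: three families sharing one presence pattern
  (query plus each other genome with probability 0.4, at least two) and
  sitting adjacent as one operon run in every shared genome — the
  classical conserved-operon signal, visible to both methods.
- Scattered planted genes act as operon-run breakers, so planted singleton
  members never share a background run (and hence never gain incidental
  strong operon edges to anything).

What passing tests on these corpora show: the method recovers linkages
carried by exactly the two evidence channels it models, at realistic edge
densities, and the baselines behave as their constructions predict. What
they do not show: performance on real corpora, where e-value distributions
are family-size dependent, operon predictions err systematically rather
than randomly, annotation groups overlap, and paralogy blurs family
boundaries. None of those effects are emulated.

## Numerical choices

- Infinite distance is represented by `math.inf` and serialized as `inf`
  in ranking TSVs; edge weights serialize via `repr` for bit-exact
  round-trips.
- Exactness tests for the shortest-path engine use dyadic-rational edge
  weights (multiples of 1/256), whose path sums are exact in binary
  floating point regardless of summation order; this lets Dijkstra be
  compared to an independent Floyd–Warshall with strict equality instead
  of a tolerance.
- All randomness (generator, control sampling, permutation) flows through
  `numpy.random.default_rng` seeded explicitly; identical configuration
  and seed reproduce byte-identical outputs end to end.

## Problem sizes

The standard corpus (2,000 genes, ≈ 3,000 edges, 30 leave-one-out runs per
sweep) completes a full benchmark — network and baseline, intact and
permuted — in a few seconds on one core; the oracle comparison covers 200
random graphs of up to 30 nodes exhaustively over all node pairs. These
sizes give stable AUC estimates (±0.01 across seeds for the intact
network) while keeping every experiment re-runnable from scratch.

## Known limitations

- The exact algebraic forms of the two weight transforms are the minimal
  forms satisfying the documented constraints (range, monotonicity
  directions, the 185 normalization, the 1e-185 floor); both are isolated
  behind `similarity_weight` / `operon_weight` so an alternative is a
  one-line change.
- Whole-genome control pools exclude the positive's fellow group members
  to avoid label leakage; the alternative (include them) would deflate
  measured performance by treating true positives as negatives.
- Each organism's replicons are treated as one genome-level gene pool;
  plasmid-aware analyses would need distinct genome ids per replicon.
- The permutation control preserves degrees but not genome membership of
  edge endpoints; a stratified permutation is not implemented.
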