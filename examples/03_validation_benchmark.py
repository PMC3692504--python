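"""Leave-one-out validation with a degree-preserving permutation control.

Every member of every planted group takes a turn as positive control: its
edges to the remaining (seed) members are masked and it is re-ranked
against 99 random genes of its genome.  TOP is the fraction of runs won
outright; AUC summarizes the positive's standing against the controls.
Repeating the sweep on a degree-preserving permuted network shows how much
of the performance lives in the network topology rather than in degrees.
"""

from genelink import benchmark, build_network, generate_corpus, preset

corpus = generate_corpus(preset("mixed"))
network = build_network(corpus.catalog, corpus.similarities, corpus.operons)

reports = benchmark(
    network,
    corpus.groups,
    corpus.catalog,
    modes=("random_control",),
    rng_seed=1,
    include_permuted=True,
)

for key, report in reports.items():
    print(f"{key:26s} TOP={report.top_precision:.3f}  "
          f"AUC={report.auc:.4f}  runs={len(report.runs)}")

intact = reports["random_control"].auc
permuted = reports["random_control_permuted"].auc
print(f"\nrelative AUC drop under permutation: {(intact - permuted) / intact:.2f}")
print("A large drop confirms the predictions exploit the arrangement of "
      "edges, not just how many each gene has.")
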