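"""Build a synthetic CUT&RUN + RNA-seq study with planted truth.

The generator plants a set of differential genes (negative-binomial counts,
|log2FC| = 2) and 300 binding peaks whose signal change is concordant with,
opposite to, or independent of the linked gene's expression change.
"""
from collections import Counter

from chromlink import (
    SimulationConfig,
    generate_gene_models,
    simulate_counts,
    simulate_fragments,
    simulate_peak_calls,
)

cfg = SimulationConfig(seed=0)
genes = generate_gene_models(cfg)
counts, groups, truth = simulate_counts(genes, cfg)
peaks, calls = simulate_peak_calls(genes, truth, cfg)
fragments = simulate_fragments(peaks, cfg)

print(f"genes: {len(genes)} on {cfg.n_chroms} chromosomes")
print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(f"planted differential genes: {len(truth.de_genes)} "
      f"(signed log2FC +/- {cfg.planted_log2fc})")
print("peak classes:", dict(Counter(truth.peak_class.values())))
print(f"caller calls: {len(calls)} rows "
      f"({cfg.n_replicates} replicates x 2 callers per peak)")
print("fragments per sample:", {s: len(f) for s, f in fragments.items()})
# Treatment samples carry more fragments because most planted binding
# changes here are gains; per-sample totals are what the differential-peak
# stage normalizes away.
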