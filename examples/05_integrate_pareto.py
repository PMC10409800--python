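"""The full integration: combined z-scores and Pareto-front selection.

Gene and peak log2 fold-changes are scaled to z-scores (z = log2FC / sd of
all fold-changes); each linked pair carries z_gp = z_g * z_p; within each
sign quadrant, non-dominated sorting on (|z_g|, |z_p|) picks the top 10
Pareto levels as the most correlated / anti-correlated pairs.
"""
from chromlink import SimulationConfig, recovery_metrics, run_pipeline

res = run_pipeline(SimulationConfig(seed=0))
pairs = res.pairs

print(f"{len(pairs)} gene-peak pairs in {pairs['quadrant'].nunique()} quadrants")
for q, grp in pairs.groupby("quadrant"):
    sel = grp["selected"].sum()
    print(f"  quadrant {q}: {len(grp):3d} pairs, {sel:3d} in the top 10 levels")
print(f"selected total: {int(pairs['selected'].sum())} "
      f"({(pairs['orientation'] == 'correlated').sum()} correlated-quadrant pairs)")

m = recovery_metrics(res)
print(f"planted concordant pairs recovered: {100 * m['sensitivity']:.1f}% "
      f"of {m['n_concordant_pairs']}")
print(f"pure-null pairs selected:           {100 * m['null_selected']:.1f}% "
      f"of {m['n_null_pairs']}")
# Sensitivity near 100% with few null selections shows the quadrant-wise
# Pareto fronts isolate the planted concordant signal from background pairs.
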