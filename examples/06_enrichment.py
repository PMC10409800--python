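"""Overlap enrichment: are differential genes enriched among bound genes?

The hypergeometric upper tail asks how surprising the observed overlap is
given the expressed-gene universe; Fisher's exact test handles small 2x2
designs such as phenotype penetrance tables.
"""
from chromlink import (
    SimulationConfig,
    fisher_exact,
    overlap_test,
    recovery_metrics,
    run_pipeline,
)

res = run_pipeline(SimulationConfig(seed=0))

universe = list(res.de_results.index)
bound = sorted(set(res.links["gene_id"]))  # genes with a peak within 50 kb
de = res.de_up + res.de_down
t = overlap_test(de, bound, universe)
print(f"universe {t.population_n} expressed genes; {t.success_k} bound; "
      f"{t.sample_n} differential; overlap {t.observed}")
print(f"hypergeometric P(X >= {t.observed}) = {t.p_tail:.3e}")
# A tiny tail probability: differential genes are far more often bound than
# chance predicts, exactly the behaviour planted by the simulator.

p = fisher_exact([[18, 1], [2, 16]])
print(f"Fisher two-sided p for [[18, 1], [2, 16]]: {p:.3e}")
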