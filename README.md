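# chromlink

Integrating chromatin-binding changes (CUT&RUN / ChIP-seq style peak calls)
with RNA-seq differential expression. `chromlink` is for analysts who have,
for a factor knockout or perturbation, (a) per-replicate peak calls from two
callers with FDRs, (b) fragment intervals per sample, and (c) a gene-level
count matrix — and who want a tested, reusable implementation of the whole
reconciliation-to-integration chain rather than a pile of one-off scripts.

## What it computes

**Peak reconciliation.** Within each replicate, calls from both callers are
unioned (≥ 1 bp single linkage) into regions: *strong* if any supporting call
has FDR < 0.05, *weak* if any has FDR < 0.5. A region is **reproducible** iff
it is strong in every replicate, or strong in at least one and at least weak
in every other. Reproducible regions are merged, fragments < 2000 bp are
counted per sample (any-overlap), and differential binding is tested with the
same moderated-t machinery as expression.

**Differential expression.** TMM normalization, removal of genes with
CPM < 1 in all samples, then a moderated two-sample t on log2(CPM + 0.5)
with the pooled per-gene variance shrunk toward the geometric-mean variance
(fixed prior df, default 4), Benjamini–Hochberg FDR, and the preranked-GSEA
metric log2FC × −log10 p.

**Annotation.** Each peak gets exactly one category by priority:
Promoter.Up ≻ Promoter.Down ≻ Exonic ≻ Intronic ≻ TES ≻ Distal5 ≻ Distal3 ≻
Intergenic (promoter/TES windows 2 kb, distal windows 50 kb,
strand-oriented, any-overlap).

**Integration.** For each gene *g* and peak *p* with the peak inside
TSS ± 50 kb:

    z_g = log2FC(g) / sd(log2FC over genes)
    z_p = log2FC(p) / sd(log2FC over peaks)
    z_{g,p} = z_g · z_p

Pairs are split by sign quadrant; within each quadrant, non-dominated
sorting on (|z_g|, |z_p|) (maximize both) assigns Pareto levels, and pairs
on the top 10 levels are the most **correlated** (++/−−) or
**anti-correlated** (+−/−+) gene–peak pairs.

**Enrichment.** Hypergeometric upper-tail overlap tests (log-gamma, stable
for genome-scale universes) and a probability-ordering two-sided Fisher's
exact test.

**Synthetic data.** A first-class simulator plants differential genes
(negative-binomial counts) and concordant / anti-concordant / null peaks
with per-replicate, per-caller calls and fragment pileups, so every stage is
testable against known truth without any external download.

## Worked example

```python
from chromlink import SimulationConfig, recovery_metrics, run_pipeline

res = run_pipeline(SimulationConfig(seed=0))
for q, grp in res.pairs.groupby("quadrant"):
    print(q, len(grp), int(grp["selected"].sum()))
print(recovery_metrics(res))
```

Running `python examples/05_integrate_pareto.py` (the same computation)
prints:

```
265 gene-peak pairs in 4 quadrants
  quadrant ++:  49 pairs,  49 in the top 10 levels
  quadrant +-:  93 pairs,  52 in the top 10 levels
  quadrant -+:  44 pairs,  44 in the top 10 levels
  quadrant --:  79 pairs,  52 in the top 10 levels
selected total: 197 (128 correlated-quadrant pairs)
planted concordant pairs recovered: 100.0% of 96
pure-null pairs selected:           4.5% of 66
```

Reading: of the 300 planted peaks, 265 fall within 50 kb of an expressed
gene's TSS and form pairs. All 96 planted concordant pairs land in the top
10 Pareto levels of the same-sign quadrants, while only 3 of 66 pairs that
pair a background peak with a non-differential gene are selected — the
quadrant-wise fronts isolate the planted signal from noise.

The other `examples/` scripts walk each capability separately (simulation,
differential expression, reconciliation, annotation, enrichment). A thin CLI
mirrors the stages:

```
chromlink simulate --outdir sim --seed 0
chromlink de --counts sim/counts.tsv --groups sim/groups.tsv --out de.tsv
chromlink run-all --outdir out --seed 0
```

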