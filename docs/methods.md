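# Methods

## The model in brief

`chromlink` treats a perturbation study as two parallel measurements of the
same genes: an expression contrast (RNA-seq counts, control vs treatment)
and a binding contrast (fragment counts in reconciled peaks). Both are
reduced to per-feature log2 fold-changes, each scaled by the standard
deviation of all fold-changes in its own result set,

z_g = log2FC(g) / sd(log2FC), z_p = log2FC(p) / sd(log2FC),

and every gene–peak pair with the peak inside TSS ± 50 kb carries the
product z_{g,p} = z_g · z_p. The sign structure is the scientific content:
same-sign pairs (quadrants ++ and −−) are candidate activation-style
targets, opposite-sign pairs (+− and −+) are candidate repression-style
targets (the natural case for a repressive chromatin mark, where binding
loss accompanies expression gain). Within each quadrant the pairs are ranked
by non-dominated sorting maximizing (|z_g|, |z_p|); the top 10 Pareto levels
are reported as the most correlated / anti-correlated pairs. Pareto ranking
rather than a threshold on z_{g,p} avoids trading one axis against the
other: a pair must be jointly extreme, not extreme in the product because
one factor is huge.

Assumptions worth stating plainly:

- The sd used for scaling is computed over *all* retained features (post
  CPM filter; all tested peaks), n−1 denominator, so z-scores are
  comparable within a result set but are not p-values.
- A zero z is assigned positive sign for quadrant membership — a
  measure-zero tie rule that only matters for degenerate inputs.
- Linking is by any-overlap of the peak interval with [TSS−50 kb,
  TSS+50 kb); one peak may serve several genes and vice versa. No attempt
  is made to decide *which* linked gene a distal peak regulates.

## Peak reconciliation

Calls from the two callers within one replicate are unioned by ≥ 1 bp
single-linkage into regions classified by the best supporting FDR: strong
(< 0.05), weak (< 0.5), else unclassified — "called by at least one
method" semantics, no reciprocal-overlap requirement. Across replicates,
linked regions form one candidate peak whose interval is the union span;
the peak is reproducible iff strong everywhere, or strong somewhere and at
least weak everywhere else. An absent replicate fails the rule. All
coordinates are 0-based half-open; book-ended intervals do not overlap and
are never merged.

Fragment counting keeps fragments strictly shorter than 2000 bp (paired-end
fragments are already "extended reads"; no further extension is applied)
and increments every peak a fragment touches by ≥ 1 bp, once per peak, with
no fractional assignment.

Score-percentile confidence classes for broad-domain callers
(`sicer_percentile_classes`) are exposed separately: top 1% high-confidence
and top 5% low-confidence by score, ceiling counts, ties broken by
(chrom, start). They are an alternative track and are not composed into the
strong/weak thresholds by default; the composition is left to the caller.

## Differential testing

Both contrasts use the same moderated two-sample t on log2(x + 0.5) of
library-normalized counts (CPM for genes; per-sample total fragment count
for peaks). The pooled per-gene variance s² (df = n₁+n₂−2) is shrunk toward
the geometric mean of the positive variances s₀² with a fixed prior weight
d₀ (default 4):

s²_post = (d₀·s₀² + df·s²) / (d₀ + df), t ~ Student(d₀ + df).

This is a deliberate simplification of the voom/limma pipeline: no
mean–variance precision weights, and the prior df is a constant rather than
estimated from an F-mixture. d₀ = 0 recovers the ordinary pooled t exactly
(a tested limiting case). The simplification is adequate here because every
downstream consumer uses only (log2FC, p, FDR), and the null calibration is
verified by simulation: under a no-effect negative-binomial model the
rejection rate at nominal 0.05 stays within [0.03, 0.07] over 5000 genes.

TMM normalization follows the published algorithm: M-values doubly trimmed
(30% per tail on M, 5% per tail on A), precision-weighted by the
delta-method variance, reference = sample whose upper-quartile CPM is
closest to the mean upper quartile, factors centered to geometric mean 1.
The implementation is cross-checked against edgeR's `calcNormFactors` in
the test suite and agrees to ~1e-6.

Numerical choices: pseudocount 0.5 before log2; p-values floored at 1e-300
before −log10 (rank metric); BH step-up with input order preserved;
strict inequalities for every selection threshold (FDR < 0.05;
fold-change > 2 ⇔ |log2FC| > 1 on the linear scale with p < 0.05).

## Annotation ladder

Evaluation stops at the first category whose window contains any base of
the peak: Promoter.Up = strand-oriented [TSS−2 kb, TSS), Promoter.Down =
[TSS, TSS+2 kb), then exon/intron overlap of any isoform (exon union;
intron = gene span minus exons), TES ± 2 kb, ≤ 50 kb upstream of TSS,
≤ 50 kb downstream of TES, else Intergenic. When several genes match the
winning category the nearest TSS anchors the peak (ties: smaller gene id).
The distal classes anchor to TSS/TES respectively, as the ladder is
written; peaks on chromosomes absent from the gene models are Intergenic.

## The synthetic study

The generator's defaults define the study conditions used throughout the
tests; they were chosen once, before the acceptance measurements, from a
geometry study of the selection stage (below), and are not tuned per run.

| parameter | default | rationale |
|---|---|---|
| genes / chromosomes | 2000 on 2 × 150 Mb | ~150 kb TSS spacing: windows disjoint, ~⅔ of random positions within 50 kb of a TSS |
| samples per group (RNA) | 4 | the profiled design |
| planted differential genes | 10% at &#124;log2FC&#124; = 2 | strong but realistic knockout effect |
| NB dispersion | 0.1 | typical bulk RNA-seq over-dispersion |
| mean expression | 2^U(3,10) counts | the post-quantification expressed-gene range; the CPM filter is a near no-op here and is exercised by unit tests |
| peaks | 300: 32% concordant, 32% anti-concordant, 36% null | see geometry note |
| peak effect | ±2 × U(0.5, 1.5) | heterogeneous binding changes, as in real differential CUT&RUN |
| replicates (CUT&RUN) | 2 per condition | the profiled design |
| call FDRs | 0.05 × Beta(1, 50); 10% demoted to [0.05, 0.5) in one replicate; 5% spurious regions in [0.5, 1) | exercises strong/weak/unclassified and the reproducibility rule |
| fragments | N(180, 40) bp, 1% ≥ 2000 bp, ~150/peak/sample + 5000 background | CUT&RUN-like pileups; outliers exercise the length filter |

Each artifact (gene models, counts, peaks, fragments) has its own RNG
stream derived from the master seed, so regenerating one does not perturb
the others; identical config + seed gives byte-identical outputs.

**Geometry of the selection stage.** The expected number of 2-D Pareto
fronts over n points in general position grows like √n and crosses 10 near
n ≈ 45. With "top 10 levels" fixed, a quadrant needs roughly 45–55 planted
pairs for the planted cloud to both fit inside 10 fronts (sensitivity) and
occupy them fully enough that background pairs are pushed beyond level 10.
The default class mix (96 concordant + 96 anti-concordant + 108 null peaks)
puts ~48 planted pairs in each of the four quadrants, which a pre-registered
simulation placed near the joint optimum of those two error rates. Equal
concordant/anti fractions are also the biologically interesting regime for a
repressive-mark factor.

**Null pairs.** For recovery metrics, a *null pair* is a null (unchanged)
peak linked to a non-differential gene. A null peak within 50 kb of a
planted differential gene forms a half-planted pair with genuine expression
signal; such pairs are usually selected (|z_g| is large) and are reported
separately. They measure the window-linkage artifact of TSS ± 50 kb
association — a known property of window-based linking — not a failure of
the Pareto stage.

**What the simulator does not emulate.** Read-level noise, mappability and
GC structure, caller-specific peak-shape statistics, biological replicate
correlation, multi-gene regulatory domains, and spike-in calibration.
Consequently, passing tests demonstrate the correctness and discriminative
behaviour of the algorithms under the planted statistical structure, not
performance on any particular real dataset. One deliberate consequence is
visible in the examples: planted gains outweigh losses, so treatment
fragment totals are higher and total-count normalization shifts every
unchanged peak slightly negative (a compositional effect; spike-in
chromatin exists to correct exactly this). The quadrant-wise Pareto ranking
is unaffected because it is rank-based within each quadrant.

## Problem sizes in the test and acceptance runs

The acceptance checks run at sizes the full suite can complete quickly
while remaining information-dense: 1000 random instances of ≤ 200 points
for the Pareto oracle; every hypergeometric instance with population ≤ 40
and every 2×2 table with total ≤ 40 against exact integer-arithmetic
enumeration; 1000 random p-vectors for BH; all 3^n reproducibility
combinations for 2 and 3 replicates; the default synthetic study (above)
for end-to-end recovery; 5000 null genes for calibration. The end-to-end
test uses seed 0, fixed before any measurement.

## Known limitations

- The moderated t is not voom: with very small counts or wildly varying
  library sizes its calibration degrades sooner than the weighted version.
- Per-sample total normalization of peak counts inherits compositional bias
  under globally asymmetric binding change (no spike-in model).
- Whether a Pareto selection should maximize signed z, |z|, or the product,
  and whether "top 10 levels" should apply per orientation or globally,
  admits several conventions; the quadrant-wise (|z_g|, |z_p|) scheme
  implemented here is a declared, symmetric choice.
- Annotation is gene-level (exon union across isoforms); no transcript-level
  or enhancer-aware assignment.
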