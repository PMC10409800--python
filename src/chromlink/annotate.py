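"""Priority genomic annotation and TSS-window gene-peak linking.

Each peak receives exactly one category, the first match in the ladder
Promoter.Up > Promoter.Down > Exonic > Intronic > TES > Distal5 > Distal3 >
Intergenic. Windows are strand-oriented: Promoter.Up is the 2 kb upstream of
the TSS, Promoter.Down the 2 kb downstream; Distal5/Distal3 extend 50 kb
upstream of the TSS / downstream of the TES. A window "contains" a peak if
any base of the peak overlaps it. For integration, a gene is associated with
every peak overlapping TSS +/- 50 kb; one peak may link to several genes.
"""
from __future__ import annotations

from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel

CATEGORIES = (
    "Promoter.Up", "Promoter.Down", "Exonic", "Intronic",
    "TES", "Distal5", "Distal3", "Intergenic",
)


def _gene_windows(g: GeneModel, promoter: int, tes_win: int, distal: int):
    """Category -> list of half-open windows for one gene (strand-oriented)."""
    if g.strand == "+":
        prom_up = (g.tss - promoter, g.tss)
        prom_down = (g.tss, g.tss + promoter)
        distal5 = (g.tss - distal, g.tss)
        distal3 = (g.tes, g.tes + distal)
    else:
        prom_up = (g.tss, g.tss + promoter)
        prom_down = (g.tss - promoter, g.tss)
        distal5 = (g.tss, g.tss + distal)
        distal3 = (g.tes - distal, g.tes)
    return {
        "Promoter.Up": [prom_up],
        "Promoter.Down": [prom_down],
        "Exonic": list(g.exons),
        "Intronic": g.introns(),
        "TES": [(g.tes - tes_win, g.tes + tes_win)],
        "Distal5": [distal5],
        "Distal3": [distal3],
    }


class GeneIndex:
    """Interval trees per (category, chrom) for priority annotation."""

    def __init__(
        self,
        genes: list[GeneModel],
        promoter_bp: int = 2000,
        tes_bp: int = 2000,
        distal_bp: int = 50_000,
    ):
        self.genes = {g.gene_id: g for g in genes}
        self.trees: dict[str, dict[str, IntervalTree]] = {
            cat: defaultdict(IntervalTree) for cat in CATEGORIES[:-1]
        }
        for g in genes:
            for cat, wins in _gene_windows(g, promoter_bp, tes_bp, distal_bp).items():
                for s, e in wins:
                    if s < e:
                        self.trees[cat][g.chrom].addi(s, e, g.gene_id)


def annotate_peak(
    peak: tuple[str, int, int], index: GeneIndex
) -> tuple[str, str | None]:
    """First matching category in the priority ladder, plus the anchor gene.

    Among genes matching the winning category, the one with the nearest TSS to
    the peak midpoint anchors the peak (ties broken by smaller gene id). Peaks
    on chromosomes absent from the gene models are Intergenic.
    """
    chrom, start, end = peak
    mid = (start + end) // 2
    for cat in CATEGORIES[:-1]:
        tree = index.trees[cat].get(chrom)
        if not tree:
            continue
        hits = tree.overlap(start, end)
        if hits:
            anchor = min(
                (abs(index.genes[h.data].tss - mid), h.data) for h in hits
            )[1]
            return cat, anchor
    return "Intergenic", None


def annotate_peaks(peaks: pd.DataFrame, index: GeneIndex) -> pd.DataFrame:
    """Vector wrapper: adds category and anchor_gene columns."""
    cats, anchors = [], []
    for p in peaks.itertuples(index=False):
        cat, anchor = annotate_peak((p.chrom, int(p.start), int(p.end)), index)
        cats.append(cat)
        anchors.append(anchor)
    out = peaks.copy()
    out["category"] = cats
    out["anchor_gene"] = anchors
    return out


def link_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: list[GeneModel],
    window: int = 50_000,
) -> pd.DataFrame:
    """All (gene, peak) pairs where the peak overlaps [TSS-window, TSS+window).

    ``distance`` is strand-oriented peak-midpoint minus TSS (negative =
    upstream of the TSS).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.chrom].addi(g.tss - window, g.tss + window, g)
    rows = []
    for p in peaks.itertuples(index=False):
        tree = trees.get(p.chrom)
        if not tree:
            continue
        pid = getattr(p, "peak_id", None) or f"{p.chrom}:{p.start}-{p.end}"
        mid = (int(p.start) + int(p.end)) // 2
        for hit in tree.overlap(int(p.start), int(p.end)):
            g = hit.data
            d = mid - g.tss
            if g.strand == "-":
                d = -d
            rows.append({"gene_id": g.gene_id, "peak_id": pid, "distance": d})
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "distance"]).sort_values(
        ["gene_id", "peak_id"], kind="mergesort"
    ).reset_index(drop=True)


def annotation_summary(annotated: pd.DataFrame) -> dict[str, float]:
    """Category percentages (to 0.1%), summing to ~100."""
    if len(annotated) == 0:
        raise ValueError("no annotated peaks")
    pct = annotated["category"].value_counts() / len(annotated) * 100.0
    return {cat: round(float(pct.get(cat, 0.0)), 1) for cat in CATEGORIES}
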