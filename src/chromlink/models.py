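"""Core domain objects shared across the pipeline.

All genomic coordinates are 0-based, half-open (BED convention). A gene is
stored as its genomic span plus strand; the transcription start and end sites
(TSS/TES) are derived, so that on the minus strand the TSS sits at the high
coordinate.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneModel:
    """One gene: span, strand and exon structure.

    ``exons`` are half-open intervals nested within ``[start, end)`` and
    non-overlapping. Introns are the gene span minus the exon union.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        """5' end of the gene (high coordinate on the minus strand)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """3' end of the gene."""
        return self.end if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        """Gene span minus the exon union."""
        out = []
        pos = self.start
        for s, e in sorted(self.exons):
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < self.end:
            out.append((pos, self.end))
        return out


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric overlap test bookkeeping.

    ``p_tail`` is the upper-tail probability P(X >= observed) of drawing
    ``sample_n`` items from a population of ``population_n`` containing
    ``success_k`` marked items.
    """

    population_n: int
    success_k: int
    sample_n: int
    observed: int
    p_tail: float

    def __post_init__(self) -> None:
        if self.observed > min(self.success_k, self.sample_n):
            raise ValueError("observed overlap exceeds min(success_k, sample_n)")
        if not 0.0 <= self.p_tail <= 1.0:
            raise ValueError("p_tail outside [0, 1]")
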