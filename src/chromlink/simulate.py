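"""Synthetic data with planted ground truth.

Emulates the statistical structure of a paired RNA-seq + CUT&RUN study of a
chromatin factor knockout: negative-binomial gene counts with a planted set of
differential genes, and peak calls from two pseudo-callers across replicates
whose signal changes are planted as *concordant* (same sign as the linked
gene's expression change), *anti-concordant* (opposite sign) or *null* (no
change). Fragment files per sample carry the per-peak signal so the
fragment-counting and differential-peak stages can be exercised end to end.

Each artifact (gene models, counts, peak calls, fragments) draws from its own
RNG stream derived from the master seed, so regenerating one artifact does not
perturb the others.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .models import GeneModel

# fixed stream ids so each artifact has an independent, reproducible RNG
_STREAMS = {"genes": 11, "counts": 23, "peaks": 37, "fragments": 53}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


@dataclass
class PlantedTruth:
    """Ground truth planted by the simulator.

    ``de_genes`` maps gene id -> signed planted log2 fold-change.
    ``peak_class`` maps peak id -> {concordant, anti-concordant, null}.
    ``expected_quadrant`` maps (gene_id, peak_id) -> (sign_g, sign_p) for the
    planted gene-peak associations.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    peak_class: dict[str, str] = field(default_factory=dict)
    peak_anchor: dict[str, str | None] = field(default_factory=dict)
    peak_signal_log2fc: dict[str, float] = field(default_factory=dict)
    expected_quadrant: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene models

_MAX_GENE_LEN = 20_000
_MIN_GENE_LEN = 2_000


def generate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Place genes on a jittered grid with guaranteed TSS spacing.

    Genes are laid out one per slot of width ``chrom_length * n_chroms /
    n_genes``; the jitter budget is chosen so that all pairwise TSS distances
    stay >= ``min_tss_spacing``, which keeps TSS +/- 50 kb windows disjoint at
    the default spacing.
    """
    rng = _rng(config, "genes")
    per_chrom = -(-config.n_genes // config.n_chroms)  # ceil
    spacing = config.chrom_length // per_chrom
    jitter_budget = spacing - config.min_tss_spacing - _MAX_GENE_LEN
    if jitter_budget < 0:
        raise ValueError(
            f"genes do not fit: slot spacing {spacing} bp cannot hold a gene of "
            f"up to {_MAX_GENE_LEN} bp with {config.min_tss_spacing} bp TSS spacing"
        )
    genes: list[GeneModel] = []
    idx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_here = min(per_chrom, config.n_genes - idx)
        for slot in range(n_here):
            gene_id = f"G{idx:05d}"
            length = int(rng.integers(_MIN_GENE_LEN, _MAX_GENE_LEN + 1))
            start = slot * spacing + int(rng.integers(0, jitter_budget + 1))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gene_id, chrom, start, end, strand,
                                   _random_exons(rng, start, end)))
            idx += 1
    return genes


def _random_exons(rng: np.random.Generator, start: int, end: int) -> tuple[tuple[int, int], ...]:
    """1-8 exons; alternating exon/intron segments filling the gene span."""
    n_ex = int(rng.integers(1, 9))
    if n_ex == 1:
        return ((start, end),)
    n_seg = 2 * n_ex - 1
    w = rng.dirichlet(np.ones(n_seg)) * (end - start)
    bounds = start + np.concatenate([[0.0], np.cumsum(w)])
    bounds = np.round(bounds).astype(int)
    bounds[-1] = end
    # degenerate zero-width segments collapse; keep only valid exon pieces
    exons = [
        (int(bounds[i]), int(bounds[i + 1]))
        for i in range(0, n_seg, 2)
        if bounds[i] < bounds[i + 1]
    ]
    return tuple(exons) if exons else ((start, end),)


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    genes: list[GeneModel], config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, str], PlantedTruth]:
    """Negative-binomial counts with a planted differential subset.

    Returns ``(counts, groups, truth)`` where ``counts`` is genes x samples,
    ``groups`` maps sample id -> {control, treatment} and ``truth`` records the
    signed planted log2 fold-changes. A ``frac_de`` subset of genes has its
    treatment-group mean shifted by ``2**planted_log2fc`` with random sign.
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    rng = _rng(config, "counts")
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    lo, hi = config.mean_expression_log_range
    base_mean = 2.0 ** rng.uniform(lo, hi, size=n)

    n_de = int(round(config.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(n)
    effect[de_idx] = signs * config.planted_log2fc

    truth = PlantedTruth(
        de_genes={gene_ids[i]: float(effect[i]) for i in de_idx}
    )

    nsg = config.n_samples_per_group
    samples = [f"ctrl_{i + 1}" for i in range(nsg)] + [f"trt_{i + 1}" for i in range(nsg)]
    groups = {s: ("control" if s.startswith("ctrl") else "treatment") for s in samples}

    mu = np.empty((n, 2 * nsg))
    mu[:, :nsg] = base_mean[:, None]
    mu[:, nsg:] = (base_mean * 2.0 ** effect)[:, None]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return df, groups, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) draws; dispersion -> 0 degenerates to Poisson."""
    if dispersion < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# peak calls

_CALLERS = ("caller_A", "caller_B")


def simulate_peak_calls(
    genes: list[GeneModel], truth: PlantedTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant peaks and emit per-replicate, per-caller calls.

    Returns ``(peaks, calls)``. ``peaks`` is the truth-level table (one row per
    planted peak: position, class, anchor gene, signal log2FC, base signal).
    ``calls`` holds one row per (peak, replicate, caller) with jittered
    boundaries and FDRs: confident calls draw FDR ~ 0.05 * Beta(1, fdr_noise)
    (always < 0.05); a ``borderline_frac`` of true peaks instead get FDR in
    [0.05, 0.5) in one replicate, and ``spurious_frac`` extra regions appear in
    a single replicate with FDR in [0.5, 1) to exercise the unclassified
    branch.

    Concordant peaks are placed within TSS +/- 2 kb of a planted differential
    gene with matching signal sign; anti-concordant with opposite sign; null
    peaks at random positions with no signal change.
    """
    rng = _rng(config, "peaks")
    n_conc = int(round(config.frac_concordant_peaks * config.n_peaks))
    n_anti = int(round(config.frac_anticoncordant_peaks * config.n_peaks))
    n_null = config.n_peaks - n_conc - n_anti

    de_ids = sorted(truth.de_genes)
    if (n_conc > 0 or n_anti > 0) and not de_ids:
        raise ValueError("no planted differential genes but concordant/anti-concordant peaks requested")
    if n_conc + n_anti > len(de_ids):
        raise ValueError(
            f"cannot anchor {n_conc + n_anti} planted peaks on {len(de_ids)} differential genes"
        )
    gene_by_id = {g.gene_id: g for g in genes}
    anchors = rng.choice(de_ids, size=n_conc + n_anti, replace=False) if de_ids else np.array([])

    het_lo, het_hi = config.peak_effect_heterogeneity
    rows = []
    pid = 0
    for j in range(n_conc + n_anti):
        cls = "concordant" if j < n_conc else "anti-concordant"
        g = gene_by_id[str(anchors[j])]
        gene_sign = np.sign(truth.de_genes[g.gene_id]) or 1.0
        sign = gene_sign if cls == "concordant" else -gene_sign
        fc = float(sign * config.peak_effect_log2fc * rng.uniform(het_lo, het_hi))
        width = int(rng.integers(400, 1201))
        center = g.tss + int(rng.integers(-1400, 1401))
        rows.append(_peak_row(pid, g.chrom, center, width, cls, g.gene_id, fc, rng))
        pid += 1
    chrom_names = sorted({g.chrom for g in genes})
    for _ in range(n_null):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        width = int(rng.integers(400, 1201))
        center = int(rng.integers(width, config.chrom_length - width))
        rows.append(_peak_row(pid, chrom, center, width, "null", None, 0.0, rng))
        pid += 1

    peaks = pd.DataFrame(rows)
    for r in rows:
        truth.peak_class[r["peak_id"]] = r["klass"]
        truth.peak_anchor[r["peak_id"]] = r["anchor_gene"]
        truth.peak_signal_log2fc[r["peak_id"]] = r["signal_log2fc"]
        if r["anchor_gene"] is not None:
            gs = int(np.sign(truth.de_genes[r["anchor_gene"]]))
            ps = int(np.sign(r["signal_log2fc"]))
            truth.expected_quadrant[(r["anchor_gene"], r["peak_id"])] = (gs, ps)
    peaks = peaks.rename(columns={"klass": "peak_class"})

    calls = _emit_calls(peaks, config, rng)
    return peaks, calls


def _peak_row(pid, chrom, center, width, klass, anchor, fc, rng):
    return {
        "peak_id": f"peak_{pid:04d}",
        "chrom": chrom,
        "start": int(center - width // 2),
        "end": int(center - width // 2 + width),
        "klass": klass,
        "anchor_gene": anchor,
        "signal_log2fc": fc,
        "base_signal": float(rng.uniform(0.7, 1.3)),
    }


def _emit_calls(peaks: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = len(peaks)
    borderline = rng.random(n) < config.borderline_frac
    borderline_rep = rng.integers(1, config.n_replicates + 1, size=n)
    recs = []
    for i, p in enumerate(peaks.itertuples(index=False)):
        for rep in range(1, config.n_replicates + 1):
            for caller in _CALLERS:
                jit = config.caller_jitter
                s = p.start + (int(rng.integers(-jit, jit + 1)) if jit else 0)
                e = p.end + (int(rng.integers(-jit, jit + 1)) if jit else 0)
                if e <= s:
                    e = s + 1
                if borderline[i] and rep == borderline_rep[i]:
                    fdr = float(rng.uniform(0.05, 0.5))
                else:
                    fdr = float(0.05 * rng.beta(1.0, config.peak_fdr_noise))
                recs.append((p.chrom, max(0, s), e, p.peak_id,
                             -10.0 * np.log10(max(fdr, 1e-12)), caller, rep, fdr))
    # spurious unclassified regions, one replicate each
    n_spur = int(round(config.spurious_frac * n))
    for j in range(n_spur):
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        width = int(rng.integers(300, 800))
        s = int(rng.integers(0, config.chrom_length - width))
        rep = int(rng.integers(1, config.n_replicates + 1))
        for caller in _CALLERS:
            fdr = float(rng.uniform(0.5, 1.0))
            recs.append((chrom, s, s + width, f"spur_{j:03d}",
                         -10.0 * np.log10(fdr), caller, rep, fdr))
    return pd.DataFrame(
        recs, columns=["chrom", "start", "end", "name", "score", "caller", "replicate", "fdr"]
    )


# ---------------------------------------------------------------------------
# fragments

def simulate_fragments(
    peaks: pd.DataFrame, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Per-sample fragment intervals (BED3) piling up inside the planted peaks.

    Sample ids are ``{ctrl,trt}_r{replicate}``. The treatment-group rate at a
    peak is scaled by ``2**signal_log2fc``, so a planted change of +1 yields a
    2:1 treatment:control fragment-count ratio in expectation. An
    ``fragment_outlier_frac`` of fragments get lengths >= 2000 bp to exercise
    the length filter; background fragments fall uniformly on the genome.
    """
    if config.fragment_length_mean <= 0 or config.fragment_length_sd < 0:
        raise ValueError("invalid fragment length distribution")
    rng = _rng(config, "fragments")
    samples = [f"{g}_r{r}" for g in ("ctrl", "trt") for r in range(1, config.n_replicates + 1)]
    out: dict[str, pd.DataFrame] = {}
    have_peaks = peaks is not None and len(peaks) > 0
    for sample in samples:
        is_trt = sample.startswith("trt")
        chroms, starts, ends = [], [], []
        if have_peaks:
            rate = config.fragments_per_peak * peaks["base_signal"].to_numpy()
            if is_trt:
                rate = rate * 2.0 ** peaks["signal_log2fc"].to_numpy()
            counts = rng.poisson(rate)
            for (p, c) in zip(peaks.itertuples(index=False), counts):
                if c == 0:
                    continue
                mid = rng.integers(p.start, p.end, size=c)
                lengths = _fragment_lengths(rng, c, config)
                s = np.maximum(0, mid - lengths // 2)
                chroms.extend([p.chrom] * int(c))
                starts.append(s)
                ends.append(s + lengths)
        nb = config.background_fragments
        if nb:
            bg_chrom = rng.integers(1, config.n_chroms + 1, size=nb)
            mid = rng.integers(0, config.chrom_length, size=nb)
            lengths = _fragment_lengths(rng, nb, config)
            s = np.maximum(0, mid - lengths // 2)
            chroms.extend(f"chr{c}" for c in bg_chrom)
            starts.append(s)
            ends.append(s + lengths)
        df = pd.DataFrame({
            "chrom": chroms,
            "start": np.concatenate(starts) if starts else np.array([], dtype=int),
            "end": np.concatenate(ends) if ends else np.array([], dtype=int),
        })
        out[sample] = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out


def _fragment_lengths(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    lengths = np.clip(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n),
        50, 1999,
    ).astype(int)
    if config.fragment_outlier_frac > 0:
        outlier = rng.random(n) < config.fragment_outlier_frac
        lengths[outlier] = rng.integers(2000, 5001, size=int(outlier.sum()))
    return lengths


# ---------------------------------------------------------------------------
# writers

def write_gene_models_tsv(genes: list[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "chrom": g.chrom, "start": g.start, "end": g.end, "strand": g.strand,
            "gene_id": g.gene_id,
            "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_groups_tsv(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample": list(groups), "group": list(groups.values())}).to_csv(
        path, sep="\t", index=False
    )


def write_peak_calls_tsv(calls: pd.DataFrame, path: str | Path, replicate: int | None = None) -> None:
    """7-column BED-like calls: chrom start end name score caller fdr."""
    df = calls if replicate is None else calls[calls["replicate"] == replicate]
    df[["chrom", "start", "end", "name", "score", "caller", "fdr"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6g"
    )


def write_narrowpeak(calls: pd.DataFrame, path: str | Path, replicate: int | None = None) -> None:
    """narrowPeak: qValue column (col 9) = -log10 FDR; pValue and summit = -1."""
    df = calls if replicate is None else calls[calls["replicate"] == replicate]
    q = -np.log10(np.maximum(df["fdr"].to_numpy(), 1e-12))
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df["name"], "score": df["score"].round().astype(int),
        "strand": ".", "signalValue": df["score"], "pValue": -1.0,
        "qValue": q, "peak": -1,
    })
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def write_truth(truth: PlantedTruth, config: SimulationConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    pd.DataFrame(
        {"gene_id": list(truth.de_genes), "planted_log2fc": list(truth.de_genes.values())}
    ).to_csv(outdir / "truth_de_genes.tsv", sep="\t", index=False)
    pd.DataFrame({
        "peak_id": list(truth.peak_class),
        "peak_class": list(truth.peak_class.values()),
        "anchor_gene": [truth.peak_anchor[p] for p in truth.peak_class],
        "signal_log2fc": [truth.peak_signal_log2fc[p] for p in truth.peak_class],
    }).to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
    manifest = {
        "config": dataclasses.asdict(config),
        "n_de_genes": len(truth.de_genes),
        "n_peaks": len(truth.peak_class),
    }
    with open(outdir / "truth_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
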