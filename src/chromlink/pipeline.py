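"""End-to-end orchestration: simulate -> expression -> peaks -> annotate ->
integrate -> enrichment, with a manifest of per-stage row counts.

The pipeline is deterministic under the simulation seed; rerunning with the
same configuration produces byte-identical outputs. Stages communicate
through plain DataFrames, so each stage can also be re-run individually from
written intermediates.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import integrate, io, peaks as pk, rnaseq, simulate
from .config import PipelineConfig, SimulationConfig
from .models import GeneModel
from .simulate import PlantedTruth

log = logging.getLogger("chromlink")


@dataclass
class PipelineResult:
    genes: list[GeneModel]
    truth: PlantedTruth
    planted_peaks: pd.DataFrame
    counts: pd.DataFrame
    groups: dict[str, str]
    de_results: pd.DataFrame
    de_up: list[str]
    de_down: list[str]
    reproducible: pd.DataFrame
    peak_counts: pd.DataFrame
    diff_peaks: pd.DataFrame
    annotated: pd.DataFrame
    links: pd.DataFrame
    pairs: pd.DataFrame
    enrichment: dict
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    sim_config: SimulationConfig,
    pipe_config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a fresh simulation and return the result bundle."""
    cfg = pipe_config or PipelineConfig(seed=sim_config.seed)
    stages = set(cfg.stages)
    _check_dependencies(stages)

    # --- simulate
    log.info("[simulate] generating gene models, counts, peaks, fragments")
    genes = simulate.generate_gene_models(sim_config)
    counts, groups, truth = simulate.simulate_counts(genes, sim_config)
    peaks_truth, calls = simulate.simulate_peak_calls(genes, truth, sim_config)
    fragments = simulate.simulate_fragments(peaks_truth, sim_config)

    # --- RNA-seq differential expression
    log.info("[rnaseq] TMM, CPM filter, moderated t")
    factors = rnaseq.tmm_factors(counts)
    kept, removed = rnaseq.filter_low_expression(counts, factors, min_cpm=cfg.cpm_min)
    de = rnaseq.differential_expression(kept, groups, factors, prior_df=cfg.prior_df)
    up, down = rnaseq.select_de_genes(de, cfg.de_criterion)

    # --- peak reconciliation and differential binding
    log.info("[peaks] confidence classes, reproducibility, fragment counting")
    regions = {
        rep: pk.classify_confidence(calls[calls["replicate"] == rep])
        for rep in sorted(calls["replicate"].unique())
    }
    repro = pk.reproducible_peaks(regions, n_replicates=sim_config.n_replicates)
    merged = repro[repro["reproducible"]][["chrom", "start", "end"]].reset_index(drop=True)
    peak_counts = pk.count_fragments_in_peaks(merged, fragments, fragment_max=cfg.fragment_max)
    frag_groups = {s: ("control" if s.startswith("ctrl") else "treatment") for s in fragments}
    lib_sizes = pd.Series({s: len(f) for s, f in fragments.items()}, dtype=float)
    dp = pk.differential_peaks(peak_counts, frag_groups, library_sizes=lib_sizes,
                               prior_df=cfg.prior_df)

    # --- annotation and linking
    log.info("[annotate] priority categories and TSS-window links")
    index = ann.GeneIndex(
        genes,
        promoter_bp=int(cfg.promoter_kb * 1000),
        tes_bp=int(cfg.tes_kb * 1000),
        distal_bp=int(cfg.link_window_kb * 1000),
    )
    merged_named = merged.copy()
    merged_named["peak_id"] = peak_counts.index
    annotated = ann.annotate_peaks(merged_named, index)
    links = ann.link_peaks_to_genes(merged_named, genes, window=int(cfg.link_window_kb * 1000))
    links = links[links["gene_id"].isin(de.index)].reset_index(drop=True)

    # --- integration
    log.info("[integrate] combined z-scores and Pareto selection")
    gene_z = pd.Series(integrate.zscores_from_fc(de["log2fc"]), index=de.index)
    peak_z = pd.Series(integrate.zscores_from_fc(dp["log2fc"]), index=dp.index)
    pairs = integrate.combine_z(links, gene_z, peak_z)
    pairs = integrate.select_top_pairs(pairs, top_levels=cfg.top_pareto_levels)

    # --- enrichment: are differential genes enriched among peak-linked genes?
    universe = list(de.index)
    bound = sorted(set(links["gene_id"]))
    de_set = up + down
    from .stats import overlap_test

    enrichment = {}
    for label, s in (("up", up), ("down", down), ("all_de", de_set)):
        if s:
            t = overlap_test(s, bound, universe)
            enrichment[label] = dataclasses.asdict(t)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": sim_config.seed,
        "rows": {
            "genes": len(genes),
            "genes_kept": len(kept),
            "genes_removed": len(removed),
            "de_up": len(up),
            "de_down": len(down),
            "calls": len(calls),
            "reproducible_peaks": int(repro["reproducible"].sum()),
            "diff_peaks": len(dp),
            "links": len(links),
            "pairs": len(pairs),
            "selected_pairs": int(pairs["selected"].sum()),
        },
        "thresholds": {
            "fdr_strong": cfg.fdr_strong, "fdr_weak": cfg.fdr_weak,
            "fragment_max": cfg.fragment_max, "link_window_kb": cfg.link_window_kb,
            "top_pareto_levels": cfg.top_pareto_levels, "cpm_min": cfg.cpm_min,
        },
    }

    result = PipelineResult(
        genes=genes, truth=truth, planted_peaks=peaks_truth,
        counts=counts, groups=groups, de_results=de,
        de_up=up, de_down=down, reproducible=repro, peak_counts=peak_counts,
        diff_peaks=dp, annotated=annotated, links=links, pairs=pairs,
        enrichment=enrichment, manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, sim_config, cfg, Path(outdir))
    return result


def _check_dependencies(stages: set[str]) -> None:
    order = ["simulate", "rnaseq", "peaks", "annotate", "integrate", "enrich"]
    needs = {
        "rnaseq": ["simulate"], "peaks": ["simulate"],
        "annotate": ["simulate", "peaks"],
        "integrate": ["rnaseq", "peaks", "annotate"],
        "enrich": ["rnaseq", "annotate"],
    }
    for st in stages:
        if st not in order:
            raise ValueError(f"unknown stage: {st}")
        for dep in needs.get(st, []):
            if dep not in stages:
                raise ValueError(f"stage '{st}' requires stage '{dep}'; run '{dep}' first")


def _write_outputs(res: PipelineResult, sim: SimulationConfig, cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    simulate.write_gene_models_tsv(res.genes, outdir / "gene_models.tsv")
    simulate.write_counts_tsv(res.counts, outdir / "counts.tsv")
    simulate.write_groups_tsv(res.groups, outdir / "groups.tsv")
    res.de_results.to_csv(outdir / "de_results.tsv", sep="\t")
    rnaseq.rank_genes(res.de_results).to_csv(outdir / "de_ranks.rnk", sep="\t",
                                             index=False, header=False)
    io.write_reproducible_bed(res.reproducible, outdir / "reproducible_peaks.bed")
    res.peak_counts.to_csv(outdir / "peak_counts.tsv", sep="\t")
    res.diff_peaks.to_csv(outdir / "diff_peaks.tsv", sep="\t")
    res.annotated.to_csv(outdir / "annotated_peaks.tsv", sep="\t", index=False)
    res.links.to_csv(outdir / "links.tsv", sep="\t", index=False)
    res.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    simulate.write_truth(res.truth, sim, outdir)
    io.write_manifest(outdir / "manifest.json", **res.manifest,
                      enrichment=res.enrichment)


# ---------------------------------------------------------------------------
# truth-based evaluation

def recovery_metrics(res: PipelineResult) -> dict[str, float]:
    """Planted-truth recovery of the Pareto selection stage.

    ``sensitivity``: fraction of planted concordant (gene, peak) pairs that
    were selected with orientation 'correlated'. ``null_selected``: fraction
    of pure-null pairs (null peak linked to a non-differential gene) that were
    selected; pairs of a null peak with a planted differential gene carry real
    expression signal and are reported separately as ``half_planted_selected``.
    """
    truth = res.truth
    pairs = res.pairs
    id_map = _match_planted_to_merged(res)
    lookup = {
        (g, p): (bool(s), o)
        for g, p, s, o in zip(pairs["gene_id"], pairs["peak_id"],
                              pairs["selected"], pairs["orientation"])
    }

    n_conc = n_conc_sel = 0
    for (gene, pid), _quad in truth.expected_quadrant.items():
        if truth.peak_class[pid] != "concordant":
            continue
        n_conc += 1
        merged_id = id_map.get(pid)
        hit = lookup.get((gene, merged_id)) if merged_id else None
        if hit and hit[0] and hit[1] == "correlated":
            n_conc_sel += 1

    null_merged = {id_map[p] for p, c in truth.peak_class.items()
                   if c == "null" and p in id_map}
    de_genes = set(truth.de_genes)
    is_null_peak = pairs["peak_id"].isin(null_merged)
    pure_null = pairs[is_null_peak & ~pairs["gene_id"].isin(de_genes)]
    half = pairs[is_null_peak & pairs["gene_id"].isin(de_genes)]
    return {
        "sensitivity": n_conc_sel / n_conc if n_conc else float("nan"),
        "null_selected": float(pure_null["selected"].mean()) if len(pure_null) else 0.0,
        "half_planted_selected": float(half["selected"].mean()) if len(half) else 0.0,
        "n_concordant_pairs": n_conc,
        "n_null_pairs": len(pure_null),
    }


def _match_planted_to_merged(res: PipelineResult) -> dict[str, str]:
    """Planted peak id -> merged (reproducible) peak id by interval overlap."""
    out: dict[str, str] = {}
    merged_by_chrom = {c: g.sort_values("start") for c, g in res.annotated.groupby("chrom")}
    for p in res.planted_peaks.itertuples(index=False):
        m = merged_by_chrom.get(p.chrom)
        if m is None:
            continue
        starts = m["start"].to_numpy()
        ends = m["end"].to_numpy()
        hit = np.flatnonzero((starts < p.end) & (ends > p.start))
        if hit.size:
            out[p.peak_id] = m["peak_id"].iloc[hit[0]]
    return out
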