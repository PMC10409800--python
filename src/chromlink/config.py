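"""Configuration objects for the simulator and the pipeline.

``SimulationConfig`` defines the synthetic study: a negative-binomial RNA-seq
experiment with planted differential genes, plus CUT&RUN-style peak calls whose
signal changes are planted as concordant, anti-concordant or null relative to
the expression changes. ``PipelineConfig`` holds the analysis thresholds; the
defaults are the published operating points (strong FDR < 0.05, weak FDR < 0.5,
fragment cap 2000 bp, promoter/TES windows 2 kb, gene-peak window 50 kb, top 10
Pareto levels, CPM filter at 1).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome / gene models
    n_chroms: int = 2
    chrom_length: int = 150_000_000
    n_genes: int = 2000
    min_tss_spacing: int = 110_000
    # RNA-seq counts
    n_samples_per_group: int = 4
    frac_de: float = 0.1
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    mean_expression_log_range: tuple[float, float] = (3.0, 10.0)
    # peak calls
    n_peaks: int = 300
    frac_concordant_peaks: float = 0.32
    frac_anticoncordant_peaks: float = 0.32
    frac_null_peaks: float = 0.36
    peak_effect_log2fc: float = 2.0
    # per-peak multiplier range on the planted effect; binding changes in real
    # data are heterogeneous in magnitude
    peak_effect_heterogeneity: tuple[float, float] = (0.5, 1.5)
    peak_fdr_noise: float = 50.0  # Beta(1, this) draws for confident calls
    borderline_frac: float = 0.1  # true peaks demoted to FDR in [0.05, 0.5) in one replicate
    spurious_frac: float = 0.05  # extra regions with FDR in [0.5, 1)
    caller_jitter: int = 50  # bp boundary jitter between the two pseudo-callers
    n_replicates: int = 2
    # fragments
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 40.0
    fragment_outlier_frac: float = 0.01  # fraction with length >= 2000
    fragments_per_peak: float = 150.0
    background_fragments: int = 5000

    def __post_init__(self) -> None:
        fracs = (
            self.frac_concordant_peaks,
            self.frac_anticoncordant_peaks,
            self.frac_null_peaks,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("peak class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("peak class fractions must sum to 1")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_samples_per_group",
                     "n_peaks", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.mean_expression_log_range
        if lo > hi:
            raise ValueError("mean_expression_log_range must be (low, high)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**_coerce_tuples(cls, raw))


@dataclass
class PipelineConfig:
    seed: int = 0
    fdr_strong: float = 0.05
    fdr_weak: float = 0.5
    fragment_max: int = 2000
    promoter_kb: float = 2.0
    tes_kb: float = 2.0
    link_window_kb: float = 50.0
    top_pareto_levels: int = 10
    cpm_min: float = 1.0
    de_criterion: str = "fdr_lt_0.05"
    prior_df: float = 4.0
    stages: tuple[str, ...] = (
        "simulate", "rnaseq", "peaks", "annotate", "integrate", "enrich",
    )

    def __post_init__(self) -> None:
        for name in ("fdr_strong", "fdr_weak", "fragment_max", "promoter_kb",
                     "tes_kb", "link_window_kb", "top_pareto_levels", "cpm_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        """Stable hash of the analysis thresholds (not the seed or stages)."""
        d = dataclasses.asdict(self)
        d.pop("seed")
        d.pop("stages")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**_coerce_tuples(cls, raw))


def _coerce_tuples(cls, raw: dict) -> dict:
    """YAML lists -> tuples for tuple-typed dataclass fields."""
    out = dict(raw)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out
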