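"""RNA-seq normalization and differential expression.

Counts are TMM-normalized (trimmed mean of M-values), genes expressed below
1 CPM in every sample are removed, and per-gene log2 fold-changes are tested
with a moderated two-sample t statistic: the pooled per-gene variance is
shrunk toward the (geometric) mean variance with a fixed prior degrees of
freedom, a simplified stand-in for the voom/limma empirical-Bayes machinery.
Downstream stages consume only (log2FC, p, FDR).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

_PSEUDOCOUNT = 0.5
_P_FLOOR = 1e-300


def _library_sizes(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(zero.index)}")
    return lib


def compute_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on effective library sizes (library x TMM factor)."""
    lib = _library_sizes(counts)
    if factors is not None:
        lib = lib * factors.reindex(lib.index)
    return counts / lib * 1e6


def filter_low_expression(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    min_cpm: float = 1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes with CPM below ``min_cpm`` in every sample.

    Returns the kept matrix (row order preserved) and the removed gene ids.
    """
    if counts.empty:
        raise ValueError("empty count matrix")
    cpm = compute_cpm(counts, factors)
    keep = (cpm >= min_cpm).any(axis=1)
    return counts.loc[keep], list(counts.index[~keep])


def tmm_factors(
    counts: pd.DataFrame,
    reference: str | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample vs the reference, M-values (log2 ratio of library-scaled
    proportions) are doubly trimmed (``trim_m`` of each tail on M, ``trim_a``
    on A) and averaged with inverse-variance (delta-method) weights; the factor
    is 2**mean. Factors are centered to geometric mean 1. The reference
    defaults to the sample whose upper-quartile CPM is closest to the mean
    upper quartile.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples for TMM")
    lib = _library_sizes(counts).to_numpy(dtype=float)
    x = counts.to_numpy(dtype=float)
    samples = list(counts.columns)

    if reference is None:
        uq = np.quantile(x / lib * 1e6, 0.75, axis=0)
        reference = samples[int(np.argmin(np.abs(uq - uq.mean())))]
    r = samples.index(reference)

    log_factors = np.zeros(len(samples))
    for j in range(len(samples)):
        if j == r:
            continue
        log_factors[j] = _tmm_pair(x[:, j], x[:, r], lib[j], lib[r], trim_m, trim_a, samples[j])
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=samples, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a, sample_name) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValueError(f"sample {sample_name} shares no commonly expressed gene with the reference")
    obs, ref = obs[ok], ref[ok]
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.abs(m).max() < 1e-6:  # identical profiles: factor 1
        return 0.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        keep = np.ones_like(keep)
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_expression(
    counts: pd.DataFrame,
    groups: dict[str, str],
    factors: pd.Series | None = None,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Moderated-t differential expression on log2(CPM + 0.5).

    log2FC is the treatment-minus-control difference of group means of
    log-CPM. The pooled per-gene variance is shrunk toward the geometric mean
    variance with weight ``prior_df``; ``prior_df=0`` recovers the ordinary
    pooled two-sample t. Returns a DataFrame indexed by gene with columns
    log2fc, p_value, fdr, mean_cpm.
    """
    ctrl = [s for s in counts.columns if groups.get(s) == "control"]
    trt = [s for s in counts.columns if groups.get(s) == "treatment"]
    missing = [s for s in counts.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("each group needs >= 2 samples for a variance estimate")

    cpm = compute_cpm(counts, factors)
    logcpm = np.log2(cpm + _PSEUDOCOUNT)
    a = logcpm[ctrl].to_numpy()
    b = logcpm[trt].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    fc = b.mean(axis=1) - a.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid

    if prior_df > 0:
        pos = s2 > 0
        s2_prior = float(np.exp(np.mean(np.log(s2[pos])))) if pos.any() else 0.0
        s2_post = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
        df_total = prior_df + df_resid
    else:
        s2_post = s2
        df_total = df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, _P_FLOOR, 1.0)

    return pd.DataFrame(
        {
            "log2fc": fc,
            "p_value": p,
            "fdr": bh_adjust(p),
            "mean_cpm": cpm.mean(axis=1).to_numpy(),
        },
        index=counts.index,
    )


def select_de_genes(results: pd.DataFrame, criterion: str) -> tuple[list[str], list[str]]:
    """Split differential genes into (up, down) lists under one of two rules.

    ``fdr_lt_0.05``: FDR < 0.05, strict. ``fc_gt_2_and_p_lt_0.05``:
    |log2FC| > 1 (fold-change > 2) and p < 0.05, both strict.
    """
    if results.empty:
        raise ValueError("empty results")
    if criterion == "fdr_lt_0.05":
        hit = results["fdr"] < 0.05
    elif criterion == "fc_gt_2_and_p_lt_0.05":
        hit = (results["log2fc"].abs() > 1.0) & (results["p_value"] < 0.05)
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    up = list(results.index[hit & (results["log2fc"] > 0)])
    down = list(results.index[hit & (results["log2fc"] < 0)])
    return up, down


def rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Preranked-GSEA metric: log2FC * -log10(p), descending; ties by gene id."""
    p = np.maximum(results["p_value"].to_numpy(dtype=float), _P_FLOOR)
    score = results["log2fc"].to_numpy(dtype=float) * (-np.log10(p))
    out = pd.DataFrame({"gene_id": results.index, "score": score})
    return out.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
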