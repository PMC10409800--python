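"""Dual-caller, multi-replicate peak reconciliation and differential peaks.

Within a replicate, calls from both callers are unioned by single-linkage
(>= 1 bp overlap) into confidence regions: *strong* if any supporting call has
FDR < 0.05, *weak* if any has FDR < 0.5, else *unclassified*. Across
replicates, a merged region is *reproducible* if it is supported by a strong
region in every replicate, or by at least one strong region with at least a
weak region in every other replicate. Fragments >= 2000 bp are discarded
before counting; differential peak statistics reuse the moderated-t machinery
on library-normalized log counts.

All intervals are 0-based half-open; book-ended intervals ([a,b) + [b,c)) do
not overlap and are not merged.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .rnaseq import differential_expression

STRONG_FDR = 0.05
WEAK_FDR = 0.5
FRAGMENT_MAX = 2000


def sicer_percentile_classes(
    domains: pd.DataFrame,
    high_pct: float = 0.01,
    low_pct: float = 0.05,
) -> pd.Series:
    """Score-percentile confidence classes for broad-domain calls.

    Domains ranked by score descending (ties broken by (chrom, start)); the
    top ``ceil(high_pct * n)`` are ``high_confidence``, the top
    ``ceil(low_pct * n)`` (a superset) ``low_confidence``, the rest ``other``.
    """
    if len(domains) == 0:
        raise ValueError("no domains")
    order = domains.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).index
    n = len(order)
    n_high = math.ceil(high_pct * n)
    n_low = math.ceil(low_pct * n)
    cls = pd.Series("other", index=domains.index, name="confidence")
    cls.loc[order[:n_low]] = "low_confidence"
    cls.loc[order[:n_high]] = "high_confidence"
    return cls


def _single_linkage_clusters(df: pd.DataFrame) -> np.ndarray:
    """Cluster ids for >= 1 bp-overlap single linkage; df must be sorted by
    (chrom, start). Book-ended intervals get distinct clusters."""
    chrom = df["chrom"].to_numpy()
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    cluster = np.zeros(len(df), dtype=int)
    cid = -1
    cur_chrom, cur_end = None, -1
    for i in range(len(df)):
        if chrom[i] != cur_chrom or start[i] >= cur_end:
            cid += 1
            cur_chrom, cur_end = chrom[i], end[i]
        else:
            cur_end = max(cur_end, end[i])
        cluster[i] = cid
    return cluster


def merge_peaks(intervals: pd.DataFrame | list[pd.DataFrame]) -> pd.DataFrame:
    """Single-linkage union of >= 1 bp-overlapping intervals per chromosome.

    Accepts one frame or a list of frames with chrom/start/end; returns merged,
    disjoint, sorted intervals.
    """
    if isinstance(intervals, list):
        intervals = pd.concat(intervals, ignore_index=True) if intervals else pd.DataFrame(
            columns=["chrom", "start", "end"]
        )
    if len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = intervals.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    cl = _single_linkage_clusters(df)
    merged = df.groupby(cl).agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
    )
    return merged.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def classify_confidence(calls: pd.DataFrame) -> pd.DataFrame:
    """Union one replicate's calls from both callers into confidence regions.

    The region class is set by the best supporting FDR from either caller
    ("called ... by at least one method"): strong < 0.05, weak < 0.5, else
    unclassified. Raises if calls carry mixed replicate ids.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "replicate", "confidence",
                                     "min_fdr", "n_calls", "callers"])
    reps = calls["replicate"].unique()
    if len(reps) > 1:
        raise ValueError(f"calls from multiple replicates: {sorted(reps)}")
    df = calls.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    cl = _single_linkage_clusters(df)
    g = df.groupby(cl)
    out = g.agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"),
        min_fdr=("fdr", "min"), n_calls=("fdr", "size"),
        callers=("caller", lambda c: ",".join(sorted(set(c)))),
    )
    out["replicate"] = reps[0]
    out["confidence"] = np.where(
        out["min_fdr"] < STRONG_FDR, "strong",
        np.where(out["min_fdr"] < WEAK_FDR, "weak", "unclassified"),
    )
    cols = ["chrom", "start", "end", "replicate", "confidence", "min_fdr", "n_calls", "callers"]
    return out[cols].sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


_RANK = {"strong": 2, "weak": 1, "unclassified": 0}


def reproducible_peaks(
    regions_by_replicate: dict | list[pd.DataFrame],
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Cross-replicate reconciliation of confidence regions.

    Regions from all replicates are linked by >= 1 bp single-linkage overlap;
    each linked cluster becomes a candidate peak whose interval is the union
    span of its supporting regions. The peak is reproducible iff it has a
    strong region in every replicate, or at least one strong region and at
    least a weak region in every other replicate. A replicate with no
    supporting region fails the rule.
    """
    if isinstance(regions_by_replicate, dict):
        frames = list(regions_by_replicate.values())
    else:
        frames = list(regions_by_replicate)
    if n_replicates is None:
        n_replicates = len(frames)
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    all_regions = pd.concat(frames, ignore_index=True)
    if len(all_regions) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "reproducible", "min_fdr", "support"])
    df = all_regions.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    cl = _single_linkage_clusters(df)
    replicates = sorted(pd.concat(frames)["replicate"].unique()) if frames else []

    rows = []
    for _, grp in df.groupby(cl):
        best = {r: "absent" for r in replicates}
        for rep, conf in zip(grp["replicate"], grp["confidence"]):
            if best[rep] == "absent" or _RANK[conf] > _RANK[best[rep]]:
                best[rep] = conf
        classes = [best[r] for r in replicates]
        present_all = all(c != "absent" for c in classes) and len(replicates) == n_replicates
        n_strong = sum(c == "strong" for c in classes)
        at_least_weak = all(c in ("strong", "weak") for c in classes)
        reproducible = present_all and (
            n_strong == n_replicates or (n_strong >= 1 and at_least_weak)
        )
        rows.append({
            "chrom": grp["chrom"].iloc[0],
            "start": int(grp["start"].min()),
            "end": int(grp["end"].max()),
            "reproducible": reproducible,
            "min_fdr": float(grp["min_fdr"].min()) if "min_fdr" in grp else np.nan,
            "support": ";".join(f"{r}:{best[r]}" for r in replicates),
        })
    out = pd.DataFrame(rows)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def count_fragments_in_peaks(
    peaks: pd.DataFrame,
    fragments: dict[str, pd.DataFrame],
    fragment_max: int = FRAGMENT_MAX,
) -> pd.DataFrame:
    """Fragment counts per (merged peak, sample).

    Fragments with length >= ``fragment_max`` (2000 bp) are discarded. A
    fragment increments every peak it overlaps by >= 1 bp. Peaks must be
    disjoint per chromosome (merged), which makes overlap lookup a sorted
    sweep.
    """
    pk = peaks.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    peak_ids = pk.index.to_numpy()
    mat = pd.DataFrame(
        0, index=pd.RangeIndex(len(pk), name="peak"), columns=list(fragments), dtype=int
    )
    by_chrom = {c: g for c, g in pk.groupby("chrom")}
    for sample, frag in fragments.items():
        if len(frag) == 0:
            continue
        lengths = frag["end"].to_numpy() - frag["start"].to_numpy()
        frag = frag[lengths < fragment_max]
        for chrom, fr in frag.groupby("chrom"):
            if chrom not in by_chrom:
                continue
            p = by_chrom[chrom]
            starts = p["start"].to_numpy()
            ends = p["end"].to_numpy()
            fs = fr["start"].to_numpy()
            fe = fr["end"].to_numpy()
            # peaks overlapping [fs, fe): first peak with end > fs .. last with start < fe
            first = np.searchsorted(ends, fs, side="right")
            last = np.searchsorted(starts, fe, side="left")
            idx = p.index.to_numpy()
            delta = np.zeros(len(pk) + 1, dtype=int)
            valid = last > first
            for f0, l0 in zip(first[valid], last[valid]):
                delta[idx[f0]] += 1
                delta[idx[l0 - 1] + 1] -= 1
            mat[sample] += np.cumsum(delta[:-1])
    if "peak_id" in pk.columns:
        mat.index = pd.Index(pk["peak_id"], name="peak_id")
    else:
        mat.index = pd.Index(
            [f"{c}:{s}-{e}" for c, s, e in zip(pk["chrom"], pk["start"], pk["end"])],
            name="peak_id",
        )
    return mat


def differential_peaks(
    peak_counts: pd.DataFrame,
    groups: dict[str, str],
    library_sizes: pd.Series | None = None,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Moderated-t differential binding on log2 normalized fragment counts.

    Normalization is by per-sample total fragment count (``library_sizes``;
    defaults to the column sums of the matrix). Same machinery and output
    columns as the expression stage.
    """
    factors = None
    if library_sizes is not None:
        # effective library = column sum x factor = supplied total
        colsum = peak_counts.sum(axis=0)
        factors = library_sizes.reindex(peak_counts.columns) / colsum
    return differential_expression(peak_counts, groups, factors=factors, prior_df=prior_df)
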