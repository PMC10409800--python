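"""Combined z-scores and Pareto-level selection of gene-peak pairs.

Expression and binding log2 fold-changes are each scaled by the standard
deviation of all fold-changes in their respective result set (z = log2FC /
sd(log2FC)); each linked gene-peak pair carries the product z_gp = z_g * z_p.
Pairs are partitioned by sign quadrant (++/--/+-/-+); within each quadrant
non-dominated sorting on (|z_g|, |z_p|), maximizing both, assigns Pareto
levels, and pairs on the top ``top_levels`` (default 10) levels are selected
as the most correlated (same-sign quadrants) or anti-correlated
(opposite-sign quadrants).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

QUADRANTS = ("++", "--", "+-", "-+")


def zscores_from_fc(log2fc) -> np.ndarray:
    """z_i = fc_i / sample sd of all fc (n-1 denominator); order preserved."""
    fc = np.asarray(log2fc, dtype=float)
    if fc.size < 2:
        raise ValueError("need >= 2 fold-changes to estimate the sd")
    sd = fc.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: all fold-changes equal (sd = 0)")
    return fc / sd


def _sign(v: float) -> str:
    # zero treated as positive: a measure-zero tie rule
    return "+" if v >= 0 else "-"


def combine_z(
    links: pd.DataFrame,
    gene_z: pd.Series | dict,
    peak_z: pd.Series | dict,
) -> pd.DataFrame:
    """One row per link with z_g, z_p, z_gp = z_g * z_p and quadrant."""
    gene_z = pd.Series(gene_z)
    peak_z = pd.Series(peak_z)
    missing_g = set(links["gene_id"]) - set(gene_z.index)
    if missing_g:
        raise KeyError(f"no z-score for linked gene(s): {sorted(missing_g)[:5]}")
    missing_p = set(links["peak_id"]) - set(peak_z.index)
    if missing_p:
        raise KeyError(f"no z-score for linked peak(s): {sorted(missing_p)[:5]}")
    zg = gene_z.loc[links["gene_id"]].to_numpy(dtype=float)
    zp = peak_z.loc[links["peak_id"]].to_numpy(dtype=float)
    out = links[["gene_id", "peak_id"]].copy()
    out["z_g"] = zg
    out["z_p"] = zp
    out["z_gp"] = zg * zp
    out["quadrant"] = [_sign(a) + _sign(b) for a, b in zip(zg, zp)]
    return out


def pareto_levels(points: np.ndarray) -> np.ndarray:
    """Non-dominated sorting levels, maximizing both objectives.

    A point dominates another iff it is >= in both coordinates and > in at
    least one; level 1 is the non-dominated front, level k the front after
    removing levels < k. Duplicate points share a level. Sequential front
    search over points sorted lexicographically descending: a point can only
    be dominated by points sorted before it, so each point lands on the first
    existing front with no dominator, scanning fronts in order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array")
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    n = len(pts)
    levels = np.zeros(n, dtype=int)
    order = np.lexsort((-pts[:, 1], -pts[:, 0]))
    # per front, members' (x, y); track max y for a fast non-dominance check
    fronts_y_max: list[float] = []
    fronts_members: list[list[int]] = []
    for i in order:
        x, y = pts[i]
        placed = False
        for f in range(len(fronts_members)):
            if fronts_y_max[f] < y:
                # nobody in this front has y >= our y => no dominator
                dominated = False
            else:
                dominated = any(
                    (pts[j, 0] >= x and pts[j, 1] >= y)
                    and (pts[j, 0] > x or pts[j, 1] > y)
                    for j in fronts_members[f]
                )
            if not dominated:
                fronts_members[f].append(i)
                fronts_y_max[f] = max(fronts_y_max[f], y)
                levels[i] = f + 1
                placed = True
                break
        if not placed:
            fronts_members.append([i])
            fronts_y_max.append(y)
            levels[i] = len(fronts_members)
    return levels


def select_top_pairs(pairs: pd.DataFrame, top_levels: int = 10) -> pd.DataFrame:
    """Quadrant-wise Pareto selection of the strongest pairs.

    Within each quadrant, levels come from non-dominated sorting on
    (|z_g|, |z_p|); a pair is selected iff its level <= ``top_levels``.
    Orientation is ``correlated`` for ++/-- and ``anti-correlated`` for
    +-/-+ quadrants.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs")
    out = pairs.copy()
    out["level"] = 0
    for q in QUADRANTS:
        m = out["quadrant"] == q
        if not m.any():
            continue
        pts = np.column_stack([out.loc[m, "z_g"].abs(), out.loc[m, "z_p"].abs()])
        out.loc[m, "level"] = pareto_levels(pts)
    out["selected"] = out["level"] <= top_levels
    out["orientation"] = np.where(
        out["quadrant"].isin(["++", "--"]), "correlated", "anti-correlated"
    )
    return out
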