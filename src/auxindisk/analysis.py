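"""Quantification of simulated auxin patterns.

A simulated bud is summarised the way the imaging pipeline summarises a real
one: auxin maxima are extracted as connected groups of high-auxin cells whose
centroid falls in the middle ring (1/3 < r < 2/3 of the tissue radius), their
angular positions are read off about the tissue centroid, and robustness is
reported as the coefficient of variation of the angular gaps between
circularly adjacent maxima (0 for perfectly even spacing).  Circular
histograms accumulate intensity in 1° sectors, aggregated 4-fold into 90
coarse bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._arrays import compile_arrays
from .mesh import TissueMesh


@dataclass
class AuxinMaximum:
    member_cells: frozenset
    centroid: np.ndarray
    angle: float        # degrees in [0, 360) about the tissue centroid
    mean_aux: float
    peak_aux: float


@dataclass
class CircularHistogram:
    fine_bins: np.ndarray    # 360 values, 1° sectors
    coarse_bins: np.ndarray  # 90 values, 4°-binned
    alignment_offset: float
    total: float


@dataclass
class RobustnessSummary:
    maxima_count: int
    mean_max_aux: float      # NaN when no maxima
    angular_cv: float        # NaN when fewer than 2 maxima
    run_id: int = 0
    genotype: str = ""
    growth_rate: float = float("nan")
    iteration: int = 0


def extract_auxin_maxima(snapshot: TissueMesh, threshold_frac: float = 0.3,
                         ring=(1 / 3, 2 / 3)) -> list:
    """Extract auxin maxima in the middle ring of a snapshot.

    Cells at or above threshold_frac of the snapshot's maximum auxin are
    grouped into connected components of the cell-adjacency graph; a
    component becomes a maximum if its auxin-weighted centroid lies at
    ring[0]*R < r < ring[1]*R, with R the largest cell-centroid distance
    from the tissue centroid.
    """
    if not snapshot.cells:
        raise ValueError("snapshot has no cells")
    arrays = compile_arrays(snapshot)
    aux = arrays.aux
    amax = aux.max()
    if amax <= 0:
        return []
    areas = np.abs(arrays.areas())
    cents = arrays.centroids()
    tissue_c = (cents * areas[:, None]).sum(axis=0) / areas.sum()
    radii = np.hypot(*(cents - tissue_c).T)
    R = radii.max()

    candidate = aux >= threshold_frac * amax
    # union-find over interior interfaces between candidate cells
    parent = np.arange(arrays.n_cells)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for p in range(arrays.n_pairs):
        i, j = arrays.pair_src[p], arrays.pair_dst[p]
        if candidate[i] and candidate[j]:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    groups: dict[int, list] = {}
    for i in np.nonzero(candidate)[0]:
        groups.setdefault(find(i), []).append(i)

    out = []
    for members in groups.values():
        idx = np.array(members)
        w = aux[idx] * areas[idx]
        if w.sum() <= 0:
            continue
        c = (cents[idx] * w[:, None]).sum(axis=0) / w.sum()
        r = math.hypot(*(c - tissue_c))
        if not (ring[0] * R < r < ring[1] * R):
            continue
        ang = math.degrees(math.atan2(c[1] - tissue_c[1], c[0] - tissue_c[0]))
        out.append(AuxinMaximum(
            member_cells=frozenset(arrays.cids[i] for i in idx),
            centroid=c, angle=ang % 360.0,
            mean_aux=float(aux[idx].mean()),
            peak_aux=float(aux[idx].max())))
    out.sort(key=lambda m: m.angle)
    return out


def angular_cv(angles) -> float:
    """CV of the circular gaps between adjacent angles (degrees).

    Gaps between circularly adjacent angles sum to 360°; returns their sample
    (n-1) standard deviation divided by their mean.  NaN for < 2 angles.
    """
    angles = np.asarray(list(angles), dtype=float)
    if len(angles) < 2:
        return float("nan")
    s = np.sort(angles % 360.0)
    gaps = np.diff(np.concatenate([s, [s[0] + 360.0]]))
    return float(np.std(gaps, ddof=1) / gaps.mean())


def summarize_run(trajectory, threshold_frac: float = 0.3,
                  ring=(1 / 3, 2 / 3)) -> RobustnessSummary:
    """Robustness summary of a trajectory's final snapshot."""
    iteration, snapshot = trajectory.snapshots[-1]
    maxima = extract_auxin_maxima(snapshot, threshold_frac, ring)
    count = len(maxima)
    mean_max = float(np.mean([m.mean_aux for m in maxima])) if maxima else float("nan")
    cv = angular_cv([m.angle for m in maxima]) if count >= 2 else float("nan")
    cfg = getattr(trajectory, "config", None)
    return RobustnessSummary(
        maxima_count=count, mean_max_aux=mean_max, angular_cv=cv,
        run_id=getattr(cfg, "seed", 0),
        genotype=getattr(getattr(cfg, "genotype", None), "name", ""),
        growth_rate=getattr(cfg, "growth_rate", float("nan")),
        iteration=iteration)


def circular_histogram(points, center, alignment_offset: float = 0.0
                       ) -> CircularHistogram:
    """Sum intensities of (position, intensity) points into 1° sectors.

    Angles are measured counterclockwise from +x about `center`, minus
    `alignment_offset`, wrapped to [0, 360).  Coarse bins aggregate the fine
    bins exactly 4-fold, so both conserve the total signal.  A point exactly
    at the center has no defined sector and is assigned to bin 0.
    """
    pts = list(points)
    if not pts:
        raise ValueError("points must be non-empty")
    center = np.asarray(center, dtype=float)
    fine = np.zeros(360)
    warned = False
    for pos, intensity in pts:
        d = np.asarray(pos, dtype=float) - center
        if d[0] == 0 and d[1] == 0:
            b = 0
            warned = True
        else:
            ang = (math.degrees(math.atan2(d[1], d[0])) - alignment_offset) % 360.0
            b = min(int(ang), 359)
        fine[b] += intensity
    coarse = fine.reshape(90, 4).sum(axis=1)
    h = CircularHistogram(fine_bins=fine, coarse_bins=coarse,
                          alignment_offset=alignment_offset,
                          total=float(fine.sum()))
    if warned:
        import warnings
        warnings.warn("point exactly at center assigned to sector 0")
    return h


def compare_ensembles(summary_table: pd.DataFrame, metric: str,
                      grouping: str) -> dict:
    """Per-group statistics plus pairwise mean (Tukey HSD) and dispersion
    (Brown-Forsythe) comparisons of `metric` across `grouping` levels."""
    df = summary_table.dropna(subset=[metric])
    groups = {k: g[metric].to_numpy() for k, g in df.groupby(grouping)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 runs")
    report = {
        "metric": metric, "grouping": grouping,
        "groups": {str(k): {"n": int(len(v)), "mean": float(v.mean()),
                            "sd": float(v.std(ddof=1)),
                            "var": float(v.var(ddof=1))}
                   for k, v in groups.items()},
        "mean_comparisons": [], "variance_comparisons": [],
    }
    degenerate = all(v.var(ddof=1) == 0 for v in groups.values())
    report["degenerate"] = degenerate
    if degenerate:
        return report

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tuk = pairwise_tukeyhsd(df[metric].to_numpy(),
                            df[grouping].astype(str).to_numpy())
    res = tuk.summary().data[1:]
    for row in res:
        g1, g2, diff, padj, lower, upper, reject = row
        report["mean_comparisons"].append({
            "group1": str(g1), "group2": str(g2),
            "mean_diff": float(diff), "p_adj": float(padj),
            "significant": bool(reject),
            "direction": ">" if diff < 0 else "<"})
    keys = sorted(groups, key=str)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            va, vb = groups[keys[a]], groups[keys[b]]
            if va.var() == 0 and vb.var() == 0:
                continue
            stat, p = stats.levene(va, vb, center="median")
            report["variance_comparisons"].append({
                "group1": str(keys[a]), "group2": str(keys[b]),
                "var1": float(va.var(ddof=1)), "var2": float(vb.var(ddof=1)),
                "statistic": float(stat), "p": float(p),
                "direction": ">" if va.var(ddof=1) > vb.var(ddof=1) else "<"})
    return report
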