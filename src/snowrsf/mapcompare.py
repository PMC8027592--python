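"""Temporal comparison of monthly Rp maps: quantile bins, weighted kappa,
category ANOVA, and subtraction maps.

All monthly relative-probability-of-use maps are binned into ten quantile
classes whose edges come from POOLING the contemporary model's Rp values
across the whole study — one common scale, reused for historical and
forecast-scenario maps alike, so bins are comparable everywhere.  Two maps
are then compared at a fixed set of random points inside the intersection
of the two periods' 99% kernel polygons with Cohen's kappa weighted by the
degree of rank disagreement: identical maps give kappa = 1, chance-level
agreement gives kappa near 0.  Kappa records fall into five comparison
categories — year-to-year within the historical period (intra_h), within
the contemporary period (intra_c), between the decades (inter_decadal),
and within the intermediate (intra_i) and severe (intra_s) forecast
scenarios — whose per-month differences are tested with a one-way ANOVA
and post-hoc Tukey HSD.  Subtraction maps (later bin minus earlier bin,
range −9..+9 for ten bins) visualise where use shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .raster import GridRaster, HomeRangePolygon, require_aligned
from .rsf import RpMap

__all__ = [
    "CATEGORIES",
    "BinnedMap",
    "KappaRecord",
    "pooled_quantile_edges",
    "bin_map",
    "sample_intersection_points",
    "weighted_kappa",
    "compare_categories",
    "subtraction_map",
]

CATEGORIES = ("intra_h", "intra_c", "inter_decadal", "intra_i", "intra_s")


@dataclass
class BinnedMap:
    """Integer bin raster (1..n_bins) plus the quantile edges that made it."""

    raster: GridRaster
    edges: np.ndarray
    month: str = ""
    year: int | str = ""
    label: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


@dataclass
class KappaRecord:
    """One pairwise map comparison."""

    month: str
    year_pair: tuple
    category: str
    kappa: float
    n_points: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown comparison category: {self.category}")


def pooled_quantile_edges(rp_maps, n_bins: int = 10) -> np.ndarray:
    """Bin edges at the pooled 1/n..(n-1)/n quantiles of many Rp maps.

    Linear-interpolation quantile convention; the outer edges are -inf and
    +inf sentinels so values outside the pooled training range fall in the
    end bins.
    """
    if len(rp_maps) == 0:
        raise ValueError("need at least one Rp map to pool")
    vals = []
    for m in rp_maps:
        raster = m.raster if isinstance(m, RpMap) else m
        vals.append(raster.values[raster.finite_mask()])
    pooled = np.concatenate(vals)
    if len(np.unique(pooled)) < n_bins:
        raise ValueError("too few distinct pooled values for quantile bins")
    interior = np.quantile(pooled, np.arange(1, n_bins) / n_bins)
    if np.any(np.diff(interior) <= 0):
        raise ValueError("degenerate pooled quantiles (massive ties)")
    return np.concatenate([[-np.inf], interior, [np.inf]])


def bin_map(rp: RpMap | GridRaster, edges: np.ndarray, month="", year="", label="") -> BinnedMap:
    """Right-closed interval lookup: bin i iff edge[i-1] < v <= edge[i]."""
    raster = rp.raster if isinstance(rp, RpMap) else rp
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 3 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with sentinels")
    ok = raster.finite_mask()
    bins = np.searchsorted(edges, raster.values, side="left").astype(float)
    bins[~ok] = np.nan
    if isinstance(rp, RpMap):
        month = month or rp.month
        year = year or rp.year
        label = label or rp.label
    return BinnedMap(raster.like(bins), edges=edges, month=month, year=year, label=label)


def sample_intersection_points(
    polyA: HomeRangePolygon, polyB: HomeRangePolygon, n: int = 1000, seed: int = 0
) -> np.ndarray:
    """n uniform points in the intersection of two home-range polygons.

    The SAME point set should be reused across every map pair of a
    comparison batch so kappas are comparable across categories.
    """
    inter = polyA.intersection(polyB)
    inside = inter.mask.values > 0
    if not inside.any():
        raise ValueError("the two polygons do not intersect")
    rows, cols = np.nonzero(inside)
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(rows), size=n)
    jit = rng.uniform(0.0, 1.0, size=(n, 2))
    cs = inter.mask.cell_size
    return np.column_stack(
        [
            inter.mask.x_origin + (cols[idx] + jit[:, 0]) * cs,
            inter.mask.y_origin + (rows[idx] + jit[:, 1]) * cs,
        ]
    )


def weighted_kappa(bins_a, bins_b, n_bins: int = 10) -> float:
    """Cohen's kappa weighted by rank disagreement.

    With linear agreement weights w_ij = 1 - |i-j|/(n_bins-1) and
    disagreement weights v = 1 - w:

        kappa = 1 - sum(v*observed) / sum(v*expected)

    where observed is the joint proportion matrix of the two bin vectors
    and expected the outer product of their marginals.  1 for identical
    vectors; near 0 for agreement at chance level.
    """
    a = np.asarray(bins_a, dtype=int)
    b = np.asarray(bins_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("bin vectors must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two points")
    if a.min() < 1 or a.max() > n_bins or b.min() < 1 or b.max() > n_bins:
        raise ValueError(f"bin labels must lie in 1..{n_bins}")
    n = len(a)
    obs = np.zeros((n_bins, n_bins))
    np.add.at(obs, (a - 1, b - 1), 1.0)
    obs /= n
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    i = np.arange(n_bins)
    v = np.abs(i[:, None] - i[None, :]) / (n_bins - 1)  # disagreement weights
    denom = float(np.sum(v * exp))
    if denom == 0:
        # both vectors constant and equal: perfect agreement by convention
        return 1.0
    return float(1.0 - np.sum(v * obs) / denom)


def bins_at_points(binned: BinnedMap, points: np.ndarray) -> np.ndarray:
    """Bin labels of a binned map at point locations."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    row, col = binned.raster.index_of(points[:, 0], points[:, 1])
    vals = binned.raster.values[row, col]
    if np.any(~np.isfinite(vals)):
        raise ValueError("a comparison point fell on a nodata cell")
    return vals.astype(int)


def compare_categories(records, month: str) -> dict:
    """One-way ANOVA plus Tukey HSD across comparison categories for a month.

    Returns ``{"anova_F", "anova_p", "tukey": DataFrame}`` where the Tukey
    table carries pairwise adjusted p-values (studentized-range) and the
    field's significance stars (*** p<0.001, ** p<0.01, * p<0.05).
    """
    rows = [r for r in records if r.month == month]
    by_cat: dict[str, list[float]] = {}
    for r in rows:
        by_cat.setdefault(r.category, []).append(r.kappa)
    usable = {c: v for c, v in by_cat.items() if len(v) >= 2}
    if len(usable) < 2:
        thin = sorted(set(by_cat) - set(usable)) or sorted(by_cat)
        raise ValueError(
            f"insufficient replication for month {month}: categories {thin}"
        )
    groups = [np.asarray(v) for v in usable.values()]
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*groups)
        if np.isnan(f_stat):  # zero within-group variance
            f_stat, p_val = 0.0, 1.0
    labels = np.concatenate([[c] * len(v) for c, v in usable.items()])
    if np.ptp(values) == 0:
        pairs = []
        cats = sorted(usable)
        for i, c1 in enumerate(cats):
            for c2 in cats[i + 1 :]:
                pairs.append({"group1": c1, "group2": c2, "meandiff": 0.0,
                              "p_adj": 1.0, "stars": ""})
        tukey_df = pd.DataFrame(pairs)
    else:
        tk = pairwise_tukeyhsd(values, labels)
        tukey_df = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        ).rename(columns={"p-adj": "p_adj"})
        tukey_df["p_adj"] = tukey_df["p_adj"].astype(float)
        tukey_df["stars"] = [
            "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            for p in tukey_df["p_adj"]
        ]
    return {"anova_F": float(f_stat), "anova_p": float(p_val), "tukey": tukey_df,
            "month": month}


def subtraction_map(later: BinnedMap, earlier: BinnedMap) -> GridRaster:
    """Cell-wise later bin minus earlier bin; the earlier map is subtracted
    from the later map, so positive cells gained preference over time.

    Range is within [-(n_bins-1), +(n_bins-1)] — −9..+9 for ten bins.
    """
    require_aligned(later.raster, earlier.raster)
    if len(later.edges) != len(earlier.edges) or not np.allclose(
        later.edges[1:-1], earlier.edges[1:-1]
    ):
        raise ValueError("maps binned on different scales")
    diff = later.raster.values - earlier.raster.values
    return later.raster.like(diff)
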