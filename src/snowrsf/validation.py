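"""Goodness-of-fit and predictive validation of the fitted RSF.

Three instruments:

* ROC AUC of the fitted logistic scores against the used/available labels.
* Kendall's tau between prediction-bin rank and the area-adjusted
  frequency of observed use — the Boyce-style calibration check: a well
  calibrated habitat model places proportionally more use in higher
  predicted bins after correcting for how much area each bin covers.
* k-fold cross-validation (default 5 folds, stratified by case) where
  each fold is held out, the model is refit on the rest, and the held-out
  used points are scored on the refit model's prediction surface.

Spatial validation (a model against used points from its own period) and
temporal validation (a model hindcast against another period's used points
and covariates) are the same computation with different inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .raster import GridRaster
from .rsf import RSFModel, RpMap, fit_rsf, predict_rp

__all__ = [
    "ValidationReport",
    "kendall_tau",
    "roc_auc",
    "area_adjusted_tau",
    "kfold_validate",
    "MIN_USED_POINTS",
]

#: Below this many used points a monthly validation is refused rather than
#: reported: tau on a near-empty bin vector is noise.
MIN_USED_POINTS = 10


@dataclass
class ValidationReport:
    """k-fold validation summary: per-fold tau and p plus their mean."""

    per_fold_tau: list
    per_fold_p: list
    n_bins: int
    k_folds: int
    mode: str = "spatial"
    auc: float = float("nan")

    @property
    def mean_tau(self) -> float:
        return float(np.mean(self.per_fold_tau))


def kendall_tau(a, b) -> tuple[float, float]:
    """Kendall's tau-b with a two-sided p-value.

    Tie-corrected (tau-b); p-values use exact enumeration for small
    tie-free samples and the normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D vectors of length >= 2")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("no variation: a vector is all ties")
    res = stats.kendalltau(a, b)
    return float(res.statistic), float(res.pvalue)


def roc_auc(model: RSFModel, design: pd.DataFrame) -> float:
    """ROC area under the curve of fitted scores vs. case labels.

    Equals the probability a random used row outscores a random available
    row, ties counted half — the rank (Mann-Whitney) formulation.
    """
    y = design["case"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, model.score(design)))


def _bin_by_quantile_classes(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign 1..n_bins by rank so each bin holds ~equal counts."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(len(values))
    return (ranks * n_bins) // len(values) + 1


def area_adjusted_tau(
    rp: RpMap | GridRaster, used_points: np.ndarray, n_bins: int = 10
) -> tuple[float, float]:
    """Calibration tau between bin rank and area-adjusted use frequency.

    The Rp surface is cut into ``n_bins`` quantile classes by cell count;
    for each bin the adjusted frequency is (used points in bin / total
    used) / (cells in bin / total cells).  Returns Kendall's tau between
    bin rank 1..n_bins and the adjusted frequencies, with its p-value.
    """
    raster = rp.raster if isinstance(rp, RpMap) else rp
    used_points = np.asarray(used_points, dtype=float).reshape(-1, 2)
    if len(used_points) < MIN_USED_POINTS:
        raise ValueError(
            f"need at least {MIN_USED_POINTS} used points for a stable tau"
        )
    ok = raster.finite_mask()
    cells = raster.values[ok]
    if len(np.unique(cells)) < n_bins:
        raise ValueError("quantile degenerate: too few distinct Rp values")
    bins_grid = np.zeros(raster.shape, dtype=int)
    bins_grid[ok] = _bin_by_quantile_classes(cells, n_bins)

    row, col = raster.index_of(used_points[:, 0], used_points[:, 1])
    pt_bins = bins_grid[row, col]
    if np.any(pt_bins == 0):
        raise ValueError("a used point fell on a nodata cell")

    n_total_cells = int(ok.sum())
    n_total_used = len(used_points)
    adj = np.empty(n_bins)
    for b in range(1, n_bins + 1):
        area_share = np.sum(bins_grid[ok] == b) / n_total_cells
        if area_share == 0:
            raise ValueError(f"bin {b} has zero area")
        use_share = np.sum(pt_bins == b) / n_total_used
        adj[b - 1] = use_share / area_share
    return kendall_tau(np.arange(1, n_bins + 1), adj)


def kfold_validate(
    design: pd.DataFrame,
    covariates_by_month: dict | None = None,
    k: int = 5,
    n_bins: int = 10,
    seed: int = 0,
    dist_floor_m: float | None = None,
    mode: str = "spatial",
    strata: str | None = None,
) -> ValidationReport:
    """Stratified k-fold cross-validation with area-adjusted-frequency tau.

    The design is split into ``k`` folds stratified by case, preserving the
    1:1 used/available balance in every training set.  For each fold the
    model is refit on the other folds and the held-out used points are
    binned on the refit model's Rp surface; the fold's tau is the
    area-adjusted-frequency tau over those bins.

    ``covariates_by_month`` maps month label to a dict of GridRasters
    (``cc``, ``sd``, ``dist``) used to rebuild the per-fold prediction
    surfaces; when omitted, held-out available rows stand in as the areal
    sample and binning happens in score space (the two agree as the
    available sample grows, since available points are uniform in area and
    the score is a monotone transform of Rp).
    """
    y = design["case"].to_numpy(dtype=int)
    if min(np.bincount(y, minlength=2)) < k:
        raise ValueError("not enough rows per class for the requested folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    taus: list[float] = []
    ps: list[float] = []
    for _, test_idx in skf.split(np.zeros(len(y)), y):
        test = design.iloc[test_idx]
        train = design.drop(design.index[test_idx])
        if len(np.unique(test["case"])) < 2 or len(np.unique(train["case"])) < 2:
            raise ValueError("a fold lost one of the two classes")
        model = fit_rsf(train, strata=strata)
        used = test[test["case"] == 1]
        if covariates_by_month is not None:
            tau, p = _tau_on_surfaces(
                model, used, covariates_by_month, n_bins, dist_floor_m
            )
        else:
            tau, p = _tau_in_score_space(model, test, n_bins)
        taus.append(tau)
        ps.append(p)
    return ValidationReport(
        per_fold_tau=taus, per_fold_p=ps, n_bins=n_bins, k_folds=k, mode=mode
    )


def _tau_on_surfaces(model, used, covariates_by_month, n_bins, dist_floor_m):
    """Bin held-out used points on per-month Rp surfaces, pool, compute tau.

    Each month's surface is cut into quantile classes by cell count, so a
    bin covers ~1/n_bins of the area in every month and bin indices pool
    cleanly across months: the pooled area share per bin stays ~1/n_bins.
    """
    counts = np.zeros(n_bins)
    area = np.zeros(n_bins)
    n_cells_total = 0
    for month, grp in used.groupby("month"):
        cov = covariates_by_month[month]
        rp = predict_rp(model, cov["sd"], cov["cc"], cov["dist"], dist_floor_m, month=month)
        ok = rp.raster.finite_mask()
        vals = rp.raster.values[ok]
        bins_grid = np.zeros(rp.raster.shape, dtype=int)
        bins_grid[ok] = _bin_by_quantile_classes(vals, n_bins)
        row, col = rp.raster.index_of(grp["x"].to_numpy(), grp["y"].to_numpy())
        pt_bins = bins_grid[row, col]
        for b in range(1, n_bins + 1):
            counts[b - 1] += np.sum(pt_bins == b)
            area[b - 1] += np.sum(bins_grid[ok] == b)
        n_cells_total += int(ok.sum())
    adj = (counts / counts.sum()) / (area / n_cells_total)
    return kendall_tau(np.arange(1, n_bins + 1), adj)


def _tau_in_score_space(model, test, n_bins):
    """Score-space fallback: held-out available rows are the areal sample."""
    used = test[test["case"] == 1]
    avail = test[test["case"] == 0]
    s_avail = model.score(avail)
    edges = np.quantile(s_avail, np.linspace(0, 1, n_bins + 1)[1:-1])
    b_used = np.searchsorted(edges, model.score(used), side="left") + 1
    b_avail = np.searchsorted(edges, s_avail, side="left") + 1
    counts = np.array([np.sum(b_used == b) for b in range(1, n_bins + 1)], dtype=float)
    area = np.array([np.sum(b_avail == b) for b in range(1, n_bins + 1)], dtype=float)
    area = np.maximum(area, 1.0)
    adj = (counts / counts.sum()) / (area / area.sum())
    return kendall_tau(np.arange(1, n_bins + 1), adj)
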