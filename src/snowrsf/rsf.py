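"""Used/available design, logistic RSF fitting, and Rp prediction.

The resource selection function (RSF) is estimated with the standard
used/available logistic design: telemetry fixes are cases (1), random
points in the population home range are controls (0) at a 1:1 ratio, and
a logistic regression of case status on canopy cover (CC), monthly mean
snow depth (SD, cm), feeding-site proximity (1/Dist_FS, 1/m), and the
snow-by-proximity interaction (SD/Dist_FS) yields slopes beta_1..beta_4.

Relative probability of use is the exponential selection surface rescaled
to [0, 1]:

    Rp = LinScale(exp(b1*CC + b2*SD + b3/Dist_FS + b4*SD/Dist_FS))
    LinScale(x_i) = (x_i - min x) / (max x - min x)

The intercept is included when fitting (standard logistic) but excluded
from prediction: the exponential RSF is defined only up to a factor, and
LinScale removes any constant anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .raster import GridRaster, HomeRangePolygon, require_aligned

__all__ = [
    "COVARIATES",
    "RSFModel",
    "RpMap",
    "SeparationError",
    "subsample_one_per_animal_day",
    "sample_available",
    "attach_covariates",
    "build_design",
    "fit_rsf",
    "lin_scale",
    "predict_rp",
    "proximity",
]

COVARIATES = ("cc", "sd", "prox", "inter")


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass
class RSFModel:
    """Fitted RSF coefficients with standard errors and fit diagnostics."""

    beta: dict
    se: dict
    intercept: float
    loglik: float
    converged: bool
    n_used: int
    n_available: int

    def linear_predictor(self, cc, sd, prox, include_intercept: bool = False):
        lp = (
            self.beta["cc"] * np.asarray(cc, dtype=float)
            + self.beta["sd"] * np.asarray(sd, dtype=float)
            + self.beta["prox"] * np.asarray(prox, dtype=float)
            + self.beta["inter"] * np.asarray(sd, dtype=float) * np.asarray(prox, dtype=float)
        )
        return lp + self.intercept if include_intercept else lp

    def score(self, design: pd.DataFrame) -> np.ndarray:
        """Selection score (linear predictor, no intercept) for design rows."""
        return self.linear_predictor(design["cc"], design["sd"], design["prox"])

    def to_dict(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "intercept": float(self.intercept),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_used": int(self.n_used),
            "n_available": int(self.n_available),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSFModel":
        return cls(**d)


@dataclass
class RpMap:
    """Relative probability-of-use surface in [0, 1] for one month/year."""

    raster: GridRaster
    month: str = ""
    year: int | str = ""
    label: str = ""
    scaling_min: float = 0.0
    scaling_max: float = 1.0
    degenerate: bool = False


def subsample_one_per_animal_day(relocations: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep one uniformly chosen fix per animal per day.

    High-rate GPS schedules produce serially autocorrelated fixes; the
    analysis thins to a single fix per animal-day before fitting.
    """
    rng = np.random.default_rng(seed)
    # a seeded random sort key makes the per-group choice reproducible
    shuffled = relocations.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
        drop=True
    )
    return (
        shuffled.groupby(["animal_id", "date"], sort=True, as_index=False)
        .first()
        .reset_index(drop=True)
    )


def sample_available(polygon: HomeRangePolygon, n: int, seed: int = 0) -> np.ndarray:
    """n points uniform over the home-range polygon's cells.

    A cell is chosen uniformly among mask cells, then the point uniformly
    within the cell — uniform over the polygon's area.
    """
    inside = polygon.mask.values > 0
    if not inside.any():
        raise ValueError("cannot sample from an empty polygon")
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = np.nonzero(inside)
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(rows), size=n)
    jit = rng.uniform(0.0, 1.0, size=(n, 2))
    cs = polygon.mask.cell_size
    x = polygon.mask.x_origin + (cols[idx] + jit[:, 0]) * cs
    y = polygon.mask.y_origin + (rows[idx] + jit[:, 1]) * cs
    return np.column_stack([x, y])


def proximity(dist_fs: GridRaster, dist_floor_m: float) -> GridRaster:
    """Reciprocal feeding-site distance with a floor at the site itself.

    1/Dist_FS is unbounded as the distance goes to zero; distances are
    floored at ``dist_floor_m`` (default: half a cell) before inversion.
    """
    if dist_floor_m <= 0:
        raise ValueError("distance floor must be positive")
    return dist_fs.like(1.0 / np.maximum(dist_fs.values, dist_floor_m))


def attach_covariates(
    points: np.ndarray,
    month,
    snow_by_month: dict,
    canopy: GridRaster,
    dist_fs: GridRaster,
    dist_floor_m: float | None = None,
) -> pd.DataFrame:
    """Covariate rows (cc, sd, prox, inter) for point locations.

    ``month`` is a scalar label or a per-point sequence; snow is read from
    that month's mean-depth raster.  Available points inherit the month of
    their paired used point, so both rows of a pair see the same snow layer.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    months = np.asarray([month] * len(points)) if np.isscalar(month) else np.asarray(month)
    if len(months) != len(points):
        raise ValueError("need one month label per point")
    first = next(iter(snow_by_month.values()))
    require_aligned(first, canopy, dist_fs)
    if dist_floor_m is None:
        dist_floor_m = canopy.cell_size / 2.0
    prox_raster = proximity(dist_fs, dist_floor_m)

    cc = canopy.values_at(points[:, 0], points[:, 1])
    px = prox_raster.values_at(points[:, 0], points[:, 1])
    sd = np.empty(len(points))
    for m in np.unique(months):
        sel = months == m
        sd[sel] = snow_by_month[m].values_at(points[sel, 0], points[sel, 1])
    return pd.DataFrame(
        {
            "x": points[:, 0],
            "y": points[:, 1],
            "month": months,
            "cc": cc,
            "sd": sd,
            "prox": px,
            "inter": sd * px,
        }
    )


def build_design(
    used: pd.DataFrame,
    polygon: HomeRangePolygon,
    snow_by_month: dict,
    canopy: GridRaster,
    dist_fs: GridRaster,
    dist_floor_m: float | None = None,
    seed: int = 0,
    clip_to_polygon: bool = True,
) -> pd.DataFrame:
    """Full used/available table at a 1:1 ratio.

    ``used`` must carry x, y, month (plus any metadata, which is kept on
    the case rows).  Available points are sampled uniformly within the
    population 99% kernel polygon and inherit their paired used point's
    month.

    By default the handful of used fixes falling outside the polygon are
    dropped: the model contrasts use against availability *within* the
    home range, and keeping fixes whose cells the availability sample can
    never reach attenuates every slope.
    """
    if clip_to_polygon:
        inside = polygon.contains(used["x"].to_numpy(), used["y"].to_numpy())
        used = used.loc[np.asarray(inside)].reset_index(drop=True)
        if len(used) == 0:
            raise ValueError("no used points inside the home-range polygon")
    pts_used = used[["x", "y"]].to_numpy()
    avail = sample_available(polygon, len(pts_used), seed=seed)
    rows_used = attach_covariates(
        pts_used, used["month"].to_numpy(), snow_by_month, canopy, dist_fs, dist_floor_m
    )
    rows_avail = attach_covariates(
        avail, used["month"].to_numpy(), snow_by_month, canopy, dist_fs, dist_floor_m
    )
    rows_used["case"] = 1
    rows_avail["case"] = 0
    for col in ("animal_id", "winter", "period"):
        if col in used.columns:
            rows_used[col] = used[col].to_numpy()
            rows_avail[col] = used[col].to_numpy()
    return pd.concat([rows_used, rows_avail], ignore_index=True)


def fit_rsf(
    design: pd.DataFrame,
    maxiter: int = 100,
    gtol: float = 1e-8,
    strata: str | None = None,
) -> RSFModel:
    """Maximum-likelihood logistic regression of case on (cc, sd, prox, inter).

    Standard errors come from the observed information matrix at the MLE.
    Raises :class:`SeparationError` on perfect separation; sets
    ``converged=False`` (with the estimates that were reached) if the
    optimizer hits the iteration cap first.

    ``strata`` names a column whose levels get separate intercepts while
    the four slopes stay shared.  When the design pools several months,
    each month has its own availability normalising constant (the sum of
    exp(beta*x) over the month's available area differs between snow-poor
    and snow-rich months), so the correctly specified used/available
    likelihood has one intercept per month; a single pooled intercept
    biases the snow slopes.  Intercepts are nuisance parameters either
    way — prediction uses the slopes only.
    """
    y = design["case"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("design must contain both used and available rows")
    X = design.loc[:, list(COVARIATES)].to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=0) == 0):
        const = [c for c, r in zip(COVARIATES, np.ptp(X, axis=0)) if r == 0]
        raise ValueError(f"constant covariate column(s): {const}")
    # standardize internally for optimizer conditioning (prox is ~1e-3
    # while its slope is ~1e2); slopes and SEs are mapped back exactly
    scale = X.std(axis=0, ddof=0)
    Xs = (X - X.mean(axis=0)) / scale
    if strata is not None:
        dummies = pd.get_dummies(design[strata]).to_numpy(dtype=float)
        Xc = np.hstack([dummies, Xs])
        n_nuis = dummies.shape[1]
    else:
        Xc = sm.add_constant(Xs, prepend=True)
        n_nuis = 1
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            try:
                res = sm.Logit(y, Xc).fit(
                    method="newton", maxiter=maxiter, tol=gtol, disp=False
                )
            except np.linalg.LinAlgError:
                res = sm.Logit(y, Xc).fit(
                    method="lbfgs", maxiter=10 * maxiter, disp=False
                )
        except (PerfectSeparationWarning, Exception) as exc:  # noqa: BLE001
            if "separation" in str(exc).lower() or "Singular" in str(exc):
                raise SeparationError("separation detected") from exc
            raise
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    beta = dict(zip(COVARIATES, params[n_nuis:] / scale))
    se = dict(zip(COVARIATES, bse[n_nuis:] / scale))
    return RSFModel(
        beta=beta,
        se=se,
        intercept=float(np.mean(params[:n_nuis])),
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_used=int(y.sum()),
        n_available=int(len(y) - y.sum()),
    )


def lin_scale(values: np.ndarray) -> tuple[np.ndarray, float, float, bool]:
    """Order-preserving affine rescale to [0, 1].

    Returns (scaled, min, max, degenerate).  When all finite values are
    equal the map is degenerate: zeros everywhere and the flag set.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("no finite values to scale")
    lo = float(np.min(values[finite]))
    hi = float(np.max(values[finite]))
    if hi == lo:
        return np.where(finite, 0.0, np.nan), lo, hi, True
    return (values - lo) / (hi - lo), lo, hi, False


def predict_rp(
    model: RSFModel,
    snow: GridRaster,
    canopy: GridRaster,
    dist_fs: GridRaster,
    dist_floor_m: float | None = None,
    month: str = "",
    year: int | str = "",
    label: str = "",
) -> RpMap:
    """Relative probability-of-use surface for one month's covariates.

    Computes w = exp(b1*CC + b2*SD + b3*prox + b4*SD*prox) cell-wise
    (no intercept) and rescales linearly to [0, 1] over the finite cells.
    A constant selection surface yields the degenerate flag and an all-zero
    map.
    """
    require_aligned(snow, canopy, dist_fs)
    if dist_floor_m is None:
        dist_floor_m = canopy.cell_size / 2.0
    prox = proximity(dist_fs, dist_floor_m)
    ok = snow.finite_mask() & canopy.finite_mask() & dist_fs.finite_mask()
    lp = model.linear_predictor(canopy.values, snow.values, prox.values)
    lp = np.where(ok, lp, np.nan)
    # exp overflow protection: LinScale is invariant to constant shifts
    w = np.exp(lp - np.nanmax(lp))
    scaled, lo, hi, degen = lin_scale(w)
    return RpMap(
        raster=snow.like(np.where(ok, scaled, np.nan)),
        month=month,
        year=year,
        label=label,
        scaling_min=lo,
        scaling_max=hi,
        degenerate=degen,
    )
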