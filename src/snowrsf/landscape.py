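"""Synthetic alpine study system: terrain, snow, feeding sites, telemetry.

Emulates the statistical structure the winter space-use analysis assumes —
a valley-to-ridge elevation gradient (~400–3500 m), daily snow depth that
increases with elevation and varies by winter month and year, a binary
canopy map, supplemental feeding sites in two densities (a sparse
"historical" configuration of ~20 sites and a dense "contemporary" one of
~95), and telemetry relocations sampled from a known ground-truth resource
selection function — so the whole pipeline is testable end to end with the
truth in hand.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import GridRaster, HomeRangePolygon, require_aligned

__all__ = [
    "ScenarioConfig",
    "TruthRSF",
    "SnowParams",
    "WINTER_MONTHS",
    "generate_dem",
    "generate_canopy",
    "generate_snow_days",
    "place_feeding_sites",
    "simulate_relocations",
]

WINTER_MONTHS = ("Nov", "Dec", "Jan", "Feb", "Mar", "Apr")

#: Baseline snowline elevation (m) per winter month: lowest in mid-winter,
#: still low in early spring when the pack lingers.
DEFAULT_SNOWLINE = {
    "Nov": 2000.0,
    "Dec": 1500.0,
    "Jan": 1100.0,
    "Feb": 1000.0,
    "Mar": 1150.0,
    "Apr": 1300.0,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """A snow regime: an upslope snowline shift plus a depth multiplier.

    ``historical`` is the reference regime (shift 0, scale 1); forecast
    regimes shift the snowline upslope and thin the pack.
    """

    label: str = "historical"
    snowline_shift_m: float = 0.0
    snow_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.snowline_shift_m < 0:
            raise ValueError("snowline shift must be >= 0")
        if not 0 < self.snow_scale <= 1:
            raise ValueError("snow_scale must lie in (0, 1]")


@dataclass(frozen=True)
class TruthRSF:
    """Ground-truth selection coefficients for the simulator.

    Signs follow winter ungulate ecology: positive canopy selection,
    avoidance of deep snow, attraction to feeding-site proximity, and a
    non-negative snow-by-proximity interaction (feeding sites matter more
    under deep snow).
    """

    beta_cc: float = 0.8          # forested vs open
    beta_sd: float = -0.05        # per cm of snow
    beta_prox: float = 300.0      # per (1/m) of proximity
    beta_inter: float = 5.0       # per (cm/m)

    def linear_predictor(self, cc, sd, prox) -> np.ndarray:
        return (
            self.beta_cc * np.asarray(cc)
            + self.beta_sd * np.asarray(sd)
            + self.beta_prox * np.asarray(prox)
            + self.beta_inter * np.asarray(sd) * np.asarray(prox)
        )


@dataclass
class SnowParams:
    """Parameters of the daily snow-depth generator.

    depth(cell, day) = max(0, lapse * (elev - snowline(month) - shift)
                              + interannual(winter, month)
                              + daily noise) * snow_scale

    ``interannual_sd_cm`` controls year-to-year depth variability per
    month: setting it high in all months gives the variable regime of the
    historical decade; suppressing it in Dec/Jan/Apr emulates the scarce
    early/late-winter snowfall of recent years.
    """

    lapse_cm_per_m: float = 0.06
    snowline_m: dict = field(default_factory=lambda: dict(DEFAULT_SNOWLINE))
    interannual_sd_cm: dict = field(
        default_factory=lambda: {m: 25.0 for m in WINTER_MONTHS}
    )
    mean_offset_cm: dict = field(default_factory=lambda: {m: 0.0 for m in WINTER_MONTHS})
    daily_sd_cm: float = 2.0
    days_per_month: int = 28
    #: optional fixed winter severity (in units of interannual SD) per
    #: winter label, e.g. {1999: -1, 2000: +1, 2001: 0}: guarantees each
    #: period spans a dry and a snowy winter, as the study decades did;
    #: residual month-level noise is drawn on top.  Winters not listed get
    #: a fully random anomaly.
    winter_effects: dict = field(default_factory=dict)
    winter_noise_frac: float = 0.4


def generate_dem(
    nrow: int = 120,
    ncol: int = 120,
    cell_size: float = 100.0,
    elev_min_m: float = 400.0,
    elev_max_m: float = 3500.0,
    roughness: float = 120.0,
    seed: int = 0,
) -> GridRaster:
    """A valley-to-ridge elevation ramp with seeded correlated noise.

    The valley axis runs west-to-east along the grid's middle row; elevation
    climbs linearly with distance from that axis and is clipped to
    ``[elev_min_m, elev_max_m]``.  ``roughness`` (m) scales smooth
    correlated noise; 0 gives the deterministic ramp.
    """
    if nrow < 1 or ncol < 1:
        raise ValueError("grid dimensions must be positive")
    if elev_min_m >= elev_max_m:
        raise ValueError("elev_min_m must be below elev_max_m")
    rows = np.arange(nrow, dtype=float)[:, None]
    axis = (nrow - 1) / 2.0
    ramp = np.abs(rows - axis) / max(axis, 1.0)  # 0 at valley, 1 at edges
    base = elev_min_m + ramp * (elev_max_m - elev_min_m)
    base = np.broadcast_to(base, (nrow, ncol)).copy()
    if roughness > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((nrow, ncol))
        noise = ndimage.gaussian_filter(noise, sigma=3.0, mode="reflect")
        noise /= max(np.std(noise), 1e-12)
        base += roughness * noise
    return GridRaster(np.clip(base, elev_min_m, elev_max_m), cell_size=cell_size)


def generate_canopy(dem: GridRaster, treeline_m: float = 1900.0, seed: int = 0,
                    p_forest_below: float = 0.7) -> GridRaster:
    """Binary canopy map: forested (1) patches below the treeline, open (0) above.

    Correlated random patches give contiguous forest stands rather than
    salt-and-pepper cells.
    """
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(dem.shape), sigma=2.0)
    thresh = np.quantile(noise, 1.0 - p_forest_below)
    canopy = ((noise > thresh) & (dem.values < treeline_m)).astype(float)
    return dem.like(canopy)


def generate_snow_days(
    dem: GridRaster,
    winter: int,
    months=WINTER_MONTHS,
    scenario: ScenarioConfig = ScenarioConfig(),
    params: SnowParams | None = None,
    seed: int = 0,
) -> tuple[list[GridRaster], list[str]]:
    """Daily snow-depth stack for one winter under a scenario.

    Returns the ordered daily layers and their month labels.  The winter
    label enters the seeding so distinct winters draw distinct interannual
    anomalies from the same parameter set.
    """
    params = params or SnowParams()
    months = tuple(months)
    bad = set(months) - set(WINTER_MONTHS)
    if bad:
        raise ValueError(f"invalid winter months: {sorted(bad)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(winter) % (2**31)]))
    elev = dem.values
    layers: list[GridRaster] = []
    labels: list[str] = []
    effect = params.winter_effects.get(winter)
    for month in months:
        snowline = params.snowline_m[month] + scenario.snowline_shift_m
        sd = params.interannual_sd_cm[month]
        if effect is None:
            inter = rng.normal(0.0, sd)
        else:
            inter = sd * effect + rng.normal(0.0, params.winter_noise_frac * sd)
        base = (
            params.lapse_cm_per_m * (elev - snowline)
            + params.mean_offset_cm[month]
            + inter
        )
        for _ in range(params.days_per_month):
            noise = rng.normal(0.0, params.daily_sd_cm, size=elev.shape)
            depth = np.maximum(0.0, base + noise) * scenario.snow_scale
            layers.append(dem.like(depth))
            labels.append(month)
    return layers, labels


def place_feeding_sites(
    n_sites: int,
    valid_mask: GridRaster,
    min_spacing_m: float,
    seed: int = 0,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Seeded placement of feeding sites at cell centres with a spacing floor.

    Rejection-samples cells of ``valid_mask`` until ``n_sites`` points at
    pairwise distance >= ``min_spacing_m`` are found; errors if the mask
    cannot accommodate the request within the retry budget.
    """
    ok = np.argwhere(valid_mask.values > 0)
    if len(ok) < n_sites:
        raise ValueError("valid mask has fewer cells than requested sites")
    rng = np.random.default_rng(seed)
    cs = valid_mask.cell_size
    chosen: list[np.ndarray] = []
    tries = 0
    while len(chosen) < n_sites:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_sites} sites at {min_spacing_m} m spacing "
                f"within {max_tries} tries"
            )
        r, c = ok[rng.integers(len(ok))]
        pt = np.array(
            [
                valid_mask.x_origin + (c + 0.5) * cs,
                valid_mask.y_origin + (r + 0.5) * cs,
            ]
        )
        if all(np.hypot(*(pt - q)) >= min_spacing_m for q in chosen):
            chosen.append(pt)
    return np.array(chosen)


def simulate_relocations(
    truth: TruthRSF,
    covariates_by_month: dict,
    home_mask: HomeRangePolygon | GridRaster,
    n_animals: int,
    days_per_month: int,
    seed: int = 0,
    period: str = "contemporary",
    winter: int = 0,
    fixes_per_day: int = 1,
) -> pd.DataFrame:
    """Telemetry fixes drawn from the ground-truth selection surface.

    For each animal-day, one home-range cell is drawn with probability
    proportional to ``exp(truth linear predictor)`` for that month's
    covariates, and the fix is placed uniformly within the cell.  Setting
    ``fixes_per_day > 1`` emulates a high-rate GPS schedule so downstream
    one-per-animal-day subsampling has something to do.

    ``covariates_by_month`` maps month label to a dict with GridRasters
    ``cc``, ``sd`` and ``prox`` (reciprocal feeding-site distance, 1/m).
    Draws are independent across days: the analysis subsamples to one fix
    per animal-day precisely to break serial autocorrelation, so a point
    process is the appropriate generative model here.
    """
    mask_raster = home_mask.mask if isinstance(home_mask, HomeRangePolygon) else home_mask
    inside = mask_raster.values > 0
    if not inside.any():
        raise ValueError("home-range mask is empty")
    rows_idx, cols_idx = np.nonzero(inside)
    cs = mask_raster.cell_size
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(winter) % (2**31)]))

    records = []
    day_counter = 0
    for month, cov in covariates_by_month.items():
        require_aligned(mask_raster, cov["cc"], cov["sd"], cov["prox"])
        lp = truth.linear_predictor(
            cov["cc"].values[inside], cov["sd"].values[inside], cov["prox"].values[inside]
        )
        lp = lp - np.max(lp)
        w = np.exp(lp)
        if not np.all(np.isfinite(w)) or w.sum() <= 0:
            raise ValueError("selection weights are zero or non-finite")
        p = w / w.sum()
        n_fix = n_animals * days_per_month * fixes_per_day
        cells = rng.choice(len(p), size=n_fix, p=p)
        jitter = rng.uniform(0.0, 1.0, size=(n_fix, 2))
        xs = mask_raster.x_origin + (cols_idx[cells] + jitter[:, 0]) * cs
        ys = mask_raster.y_origin + (rows_idx[cells] + jitter[:, 1]) * cs
        k = 0
        for day in range(days_per_month):
            for animal in range(n_animals):
                for _ in range(fixes_per_day):
                    records.append(
                        {
                            "animal_id": f"{period[:1]}{animal:03d}",
                            "date": f"w{winter}-{month}-{day + 1:02d}",
                            "month": month,
                            "x": xs[k],
                            "y": ys[k],
                            "period": period,
                            "winter": winter,
                        }
                    )
                    k += 1
            day_counter += 1
    return pd.DataFrame.from_records(records)
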