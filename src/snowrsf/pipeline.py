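"""End-to-end experiment orchestration.

Runs the whole winter space-use analysis on the synthetic study system:

    simulate landscape & telemetry
      -> subsample one fix per animal-day
      -> 99% kernel home ranges per period
      -> used/available design & logistic RSF per period
      -> monthly relative-probability-of-use (Rp) maps
         (each period with its own model; forecast scenarios with the
          contemporary model)
      -> ROC AUC + 5-fold cross-validation per period
      -> pooled quantile binning, weighted-kappa map comparison across the
         five categories, per-month ANOVA + Tukey
      -> subtraction maps for early/mid/late winter

Every stage draws its randomness from a seed derived deterministically
from the master seed and the stage name, so a config maps to one result.
"""

from __future__ import annotations

import hashlib
import itertools
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landscape as ls
from . import mapcompare as mc
from . import raster as ra
from . import rsf
from . import validation as va

__all__ = ["RunConfig", "ExperimentResult", "stage_seed", "run_experiment"]

WINTER_MONTHS = ls.WINTER_MONTHS


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PeriodConfig:
    """One study period: its winters, feeding sites, snow regime, and the
    ground-truth selection behaviour its animals follow (None: the run's
    shared default truth)."""

    name: str
    winters: tuple
    n_sites: int
    min_spacing_m: float
    fixes_per_day: int
    interannual_sd_cm: dict
    mean_offset_cm: dict
    truth: ls.TruthRSF | None = None


@dataclass
class RunConfig:
    """Full experiment configuration with the default study conditions.

    The defaults emulate the study contrast: a sparse-feeding historical
    period (20 sites) with high year-to-year snow variability in every
    winter month, and a dense-feeding contemporary period (95 sites) whose
    early (Dec), mid-early (Jan) and late (Apr) winters have become
    snow-scarce and much less variable; two forecast regimes shift the
    snowline further upslope and thin the pack.
    """

    workdir: str | None = None
    master_seed: int = 0
    # landscape
    nrow: int = 110
    ncol: int = 110
    cell_size: float = 100.0
    elev_min_m: float = 400.0
    elev_max_m: float = 3500.0
    roughness_m: float = 120.0
    treeline_m: float = 1900.0
    valley_max_elev_m: float = 1300.0   # feeding sites placed below this
    # telemetry
    n_animals: int = 8
    days_per_month: int = 28
    months: tuple = WINTER_MONTHS
    truth: ls.TruthRSF = field(default_factory=ls.TruthRSF)
    # analysis constants
    n_bins: int = 10
    k_folds: int = 5
    n_compare_points: int = 1000
    isopleth_level: float = 0.99
    dist_floor_m: float | None = None
    anova_exclude_months: tuple = ("Nov",)
    # snow physics
    lapse_cm_per_m: float = 0.06
    daily_sd_cm: float = 2.0
    # periods & scenarios
    periods: tuple = ()
    scenarios: tuple = (
        ls.ScenarioConfig("intermediate", snowline_shift_m=350.0, snow_scale=0.9),
        ls.ScenarioConfig("severe", snowline_shift_m=700.0, snow_scale=0.8),
    )

    def __post_init__(self) -> None:
        bad = set(self.months) - set(WINTER_MONTHS)
        if bad:
            raise ValueError(f"invalid winter months: {sorted(bad)}")
        if not self.periods:
            hi = {m: (35.0 if m in ("Dec", "Apr") else 25.0) for m in WINTER_MONTHS}
            lo = {m: (4.0 if m in ("Dec", "Jan", "Apr") else 25.0) for m in WINTER_MONTHS}
            # decadal snow decline: scarcer throughout, most in early/late winter
            off = {m: (-15.0 if m in ("Dec", "Jan", "Apr") else -10.0) for m in WINTER_MONTHS}
            self.periods = (
                PeriodConfig(
                    name="historical",
                    winters=(1999, 2000, 2001),
                    n_sites=20,
                    min_spacing_m=400.0,
                    fixes_per_day=1,
                    interannual_sd_cm=hi,
                    mean_offset_cm={m: 0.0 for m in WINTER_MONTHS},
                    # sparse feeding, deep-snow decade: stronger snow
                    # avoidance and a much stronger snow-by-feeding-site
                    # interaction than the contemporary default truth
                    truth=ls.TruthRSF(
                        beta_cc=1.4, beta_sd=-0.05, beta_prox=450.0, beta_inter=5.0
                    ),
                ),
                PeriodConfig(
                    name="contemporary",
                    winters=(2012, 2013, 2014),
                    n_sites=95,
                    min_spacing_m=250.0,
                    fixes_per_day=2,
                    interannual_sd_cm=lo,
                    mean_offset_cm=off,
                ),
            )

    def snow_params(self, period: PeriodConfig) -> ls.SnowParams:
        # each period spans a dry, an average and a snowy winter
        effects = dict(zip(period.winters, (-1.0, 1.0, 0.0)))
        return ls.SnowParams(
            lapse_cm_per_m=self.lapse_cm_per_m,
            interannual_sd_cm=dict(period.interannual_sd_cm),
            mean_offset_cm=dict(period.mean_offset_cm),
            daily_sd_cm=self.daily_sd_cm,
            days_per_month=self.days_per_month,
            winter_effects=effects,
        )


@dataclass
class ExperimentResult:
    """Everything the pipeline computed, in memory."""

    config: RunConfig
    dem: ra.GridRaster
    canopy: ra.GridRaster
    sites: dict
    dist_fs: dict
    snow_monthly: dict      # (period/scenario label, winter) -> {month: GridRaster}
    snow_cover: dict        # (label, winter) -> GridRaster of cover days
    relocations: dict       # period -> DataFrame (subsampled)
    polygons: dict          # period -> HomeRangePolygon
    designs: dict           # period -> DataFrame
    models: dict            # period -> RSFModel
    rp_maps: dict           # (label, winter, month) -> RpMap
    edges: np.ndarray
    compare_points: np.ndarray
    kappa_records: list
    anova: dict             # month -> compare_categories output
    validation: dict        # period -> {"auc": float, "kfold": ValidationReport}
    subtraction: dict       # (month, later key, earlier key) -> GridRaster
    manifest: dict

    def kappa_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "month": r.month,
                    "year_a": r.year_pair[0],
                    "year_b": r.year_pair[1],
                    "category": r.category,
                    "kappa": r.kappa,
                    "n_points": r.n_points,
                }
                for r in self.kappa_records
            ]
        )


# ----------------------------------------------------------------------
# stage helpers

def _simulate_landscape(cfg: RunConfig):
    dem = ls.generate_dem(
        cfg.nrow, cfg.ncol, cfg.cell_size, cfg.elev_min_m, cfg.elev_max_m,
        cfg.roughness_m, seed=stage_seed(cfg.master_seed, "dem"),
    )
    canopy = ls.generate_canopy(
        dem, treeline_m=cfg.treeline_m, seed=stage_seed(cfg.master_seed, "canopy")
    )
    return dem, canopy


def _monthly_covariates(cfg, snow_by_month, canopy, dist_fs):
    floor = cfg.dist_floor_m or cfg.cell_size / 2.0
    prox = rsf.proximity(dist_fs, floor)
    return {
        m: {"cc": canopy, "sd": snow_by_month[m], "prox": prox, "dist": dist_fs}
        for m in snow_by_month
    }


def _key(winter, month):
    return f"{winter}:{month}"


def run_experiment(config: RunConfig | None = None) -> ExperimentResult:
    """Execute the full experiment; write artifacts if a workdir is set."""
    cfg = config or RunConfig()
    dem, canopy = _simulate_landscape(cfg)
    valley = dem.like((dem.values < cfg.valley_max_elev_m).astype(float))
    # the animals' true availability is the whole landscape: the winter
    # range limit emerges from snow avoidance, not from a hard fence
    range_mask = dem.like(np.ones(dem.shape))

    sites: dict = {}
    dist_fs: dict = {}
    for p in cfg.periods:
        sites[p.name] = ls.place_feeding_sites(
            p.n_sites, valley, p.min_spacing_m,
            seed=stage_seed(cfg.master_seed, f"sites:{p.name}"),
        )
        dist_fs[p.name] = ra.path_distance_3d(dem, sites[p.name])

    # --- snow series per period winter (+ scenario variants of the
    # contemporary winters, mirroring forecast-corrected recent snow)
    snow_monthly: dict = {}
    snow_cover: dict = {}
    baseline = ls.ScenarioConfig("historical")
    contemporary = cfg.periods[-1]
    for p in cfg.periods:
        params = cfg.snow_params(p)
        for w in p.winters:
            daily, labels = ls.generate_snow_days(
                dem, w, cfg.months, baseline, params,
                seed=stage_seed(cfg.master_seed, f"snow:{p.name}"),
            )
            snow_monthly[(p.name, w)] = ra.monthly_mean_snow(daily, labels)
            snow_cover[(p.name, w)] = ra.snow_cover_days(daily)
    for sc in cfg.scenarios:
        params = cfg.snow_params(contemporary)
        for w in contemporary.winters:
            daily, labels = ls.generate_snow_days(
                dem, w, cfg.months, sc, params,
                seed=stage_seed(cfg.master_seed, f"snow:{contemporary.name}"),
            )
            snow_monthly[(sc.label, w)] = ra.monthly_mean_snow(daily, labels)
            snow_cover[(sc.label, w)] = ra.snow_cover_days(daily)

    # --- telemetry, home ranges, designs, models
    relocations: dict = {}
    polygons: dict = {}
    designs: dict = {}
    models: dict = {}
    floor = cfg.dist_floor_m or cfg.cell_size / 2.0
    for p in cfg.periods:
        truth = p.truth or cfg.truth
        prox = rsf.proximity(dist_fs[p.name], floor)
        fixes = []
        for w in p.winters:
            cov = {
                m: {"cc": canopy, "sd": snow_monthly[(p.name, w)][m], "prox": prox}
                for m in cfg.months
            }
            fixes.append(
                ls.simulate_relocations(
                    truth, cov, range_mask, cfg.n_animals, cfg.days_per_month,
                    seed=stage_seed(cfg.master_seed, f"telemetry:{p.name}"),
                    period=p.name, winter=w, fixes_per_day=p.fixes_per_day,
                )
            )
        raw = pd.concat(fixes, ignore_index=True)
        used = rsf.subsample_one_per_animal_day(
            raw, seed=stage_seed(cfg.master_seed, f"subsample:{p.name}")
        )
        relocations[p.name] = used
        polygons[p.name] = ra.kde_isopleth(
            used[["x", "y"]].to_numpy(), cfg.isopleth_level, dem
        )
        parts = []
        for w in p.winters:
            uw = used[used["winter"] == w].copy()
            uw["month_label"] = uw["month"]
            uw["month"] = [_key(w, m) for m in uw["month"]]
            snow_keyed = {_key(w, m): r for m, r in snow_monthly[(p.name, w)].items()}
            parts.append(
                rsf.build_design(
                    uw, polygons[p.name], snow_keyed, canopy, dist_fs[p.name],
                    floor, seed=stage_seed(cfg.master_seed, f"available:{p.name}:{w}"),
                )
            )
        designs[p.name] = pd.concat(parts, ignore_index=True)
        models[p.name] = rsf.fit_rsf(designs[p.name], strata="month")

    # --- monthly Rp maps: each period with its model; scenarios with the
    # contemporary model and contemporary feeding sites
    rp_maps: dict = {}
    for p in cfg.periods:
        for w in p.winters:
            for m in cfg.months:
                rp_maps[(p.name, w, m)] = rsf.predict_rp(
                    models[p.name], snow_monthly[(p.name, w)][m], canopy,
                    dist_fs[p.name], floor, month=m, year=w, label=p.name,
                )
    for sc in cfg.scenarios:
        for w in contemporary.winters:
            for m in cfg.months:
                rp_maps[(sc.label, w, m)] = rsf.predict_rp(
                    models[contemporary.name], snow_monthly[(sc.label, w)][m],
                    canopy, dist_fs[contemporary.name], floor,
                    month=m, year=w, label=sc.label,
                )

    # --- validation
    validation: dict = {}
    for p in cfg.periods:
        cov_by_key = {}
        for w in p.winters:
            for m in cfg.months:
                cov_by_key[_key(w, m)] = {
                    "cc": canopy,
                    "sd": snow_monthly[(p.name, w)][m],
                    "dist": dist_fs[p.name],
                }
        report = va.kfold_validate(
            designs[p.name], cov_by_key, k=cfg.k_folds, n_bins=cfg.n_bins,
            seed=stage_seed(cfg.master_seed, f"kfold:{p.name}"),
            dist_floor_m=floor,
            strata="month",
        )
        validation[p.name] = {
            "auc": va.roc_auc(models[p.name], designs[p.name]),
            "kfold": report,
        }

    # --- map comparison on the common scale
    hist, cont = cfg.periods[0], cfg.periods[-1]
    pooled = [
        rp_maps[(cont.name, w, m)] for w in cont.winters for m in cfg.months
    ]
    edges = mc.pooled_quantile_edges(pooled, cfg.n_bins)
    points = mc.sample_intersection_points(
        polygons[hist.name], polygons[cont.name], cfg.n_compare_points,
        seed=stage_seed(cfg.master_seed, "compare-points"),
    )
    binned = {
        key: mc.bin_map(rp, edges) for key, rp in rp_maps.items()
    }
    records: list[mc.KappaRecord] = []

    def _kappa(month, key_a, key_b, category):
        ba = mc.bins_at_points(binned[key_a], points)
        bb = mc.bins_at_points(binned[key_b], points)
        records.append(
            mc.KappaRecord(
                month=month,
                year_pair=(f"{key_a[0]}:{key_a[1]}", f"{key_b[0]}:{key_b[1]}"),
                category=category,
                kappa=mc.weighted_kappa(ba, bb, cfg.n_bins),
                n_points=len(points),
            )
        )

    intra = {
        "intra_h": (hist.name, hist.winters),
        "intra_c": (cont.name, cont.winters),
        "intra_i": (cfg.scenarios[0].label, cont.winters),
        "intra_s": (cfg.scenarios[1].label, cont.winters),
    }
    for m in cfg.months:
        for cat, (label, winters) in intra.items():
            for wa, wb in itertools.combinations(winters, 2):
                _kappa(m, (label, wa, m), (label, wb, m), cat)
        for wa in hist.winters:
            for wb in cont.winters:
                _kappa(m, (hist.name, wa, m), (cont.name, wb, m), "inter_decadal")

    anova = {
        m: mc.compare_categories(records, m)
        for m in cfg.months
        if m not in cfg.anova_exclude_months
    }

    # --- subtraction maps: within each period and vs the severe scenario,
    # low-snow winter against high-snow winter, for early/mid/late winter
    subtraction: dict = {}
    sub_months = [m for m in ("Dec", "Feb", "Apr") if m in cfg.months]
    severe = cfg.scenarios[-1].label
    for p in cfg.periods:
        totals = {w: float(np.sum(snow_cover[(p.name, w)].values)) for w in p.winters}
        dry = min(totals, key=totals.get)
        snowy = max(totals, key=totals.get)
        for m in sub_months:
            subtraction[(m, f"{p.name}:{dry}", f"{p.name}:{snowy}")] = mc.subtraction_map(
                binned[(p.name, dry, m)], binned[(p.name, snowy, m)]
            )
    for w in cont.winters:
        for m in sub_months:
            subtraction[(m, f"{severe}:{w}", f"{cont.name}:{w}")] = mc.subtraction_map(
                binned[(severe, w, m)], binned[(cont.name, w, m)]
            )

    result = ExperimentResult(
        config=cfg, dem=dem, canopy=canopy, sites=sites, dist_fs=dist_fs,
        snow_monthly=snow_monthly, snow_cover=snow_cover,
        relocations=relocations, polygons=polygons, designs=designs,
        models=models, rp_maps=rp_maps, edges=edges, compare_points=points,
        kappa_records=records, anova=anova, validation=validation,
        subtraction=subtraction, manifest={},
    )
    if cfg.workdir is not None:
        result.manifest = write_artifacts(result, Path(cfg.workdir))
    return result


def run_recovery(
    seed: int = 0,
    n_animals: int = 24,
    winters: tuple = (2013, 2014),
    days_per_month: int = 28,
    truth: ls.TruthRSF | None = None,
    cfg: RunConfig | None = None,
) -> dict:
    """Single-period parameter-recovery run: simulate, design, fit.

    Generates a landscape, simulates relocations from a known
    :class:`TruthRSF`, runs the full design path (one-per-animal-day
    subsample, 99% kernel polygon, 1:1 available sample, covariate
    attachment) and fits the stratified logistic RSF.  Returns the truth,
    the fitted model, the design, and per-slope z-distances
    (beta_hat - beta_true) / SE.
    """
    cfg = cfg or RunConfig(master_seed=seed)
    truth = truth or ls.TruthRSF()
    dem, canopy = _simulate_landscape(cfg)
    valley = dem.like((dem.values < cfg.valley_max_elev_m).astype(float))
    sites = ls.place_feeding_sites(
        95, valley, 250.0, seed=stage_seed(seed, "sites:recovery")
    )
    dist = ra.path_distance_3d(dem, sites)
    floor = cfg.dist_floor_m or cfg.cell_size / 2.0
    prox = rsf.proximity(dist, floor)
    full = dem.like(np.ones(dem.shape))
    params = cfg.snow_params(cfg.periods[-1])

    fixes = []
    snows = {}
    for w in winters:
        daily, labels = ls.generate_snow_days(
            dem, w, cfg.months, ls.ScenarioConfig("historical"), params,
            seed=stage_seed(seed, "snow:recovery"),
        )
        snows[w] = ra.monthly_mean_snow(daily, labels)
        cov = {m: {"cc": canopy, "sd": snows[w][m], "prox": prox} for m in cfg.months}
        fixes.append(
            ls.simulate_relocations(
                truth, cov, full, n_animals, days_per_month,
                seed=stage_seed(seed, "telemetry:recovery"),
                winter=w, fixes_per_day=2,
            )
        )
    raw = pd.concat(fixes, ignore_index=True)
    used = rsf.subsample_one_per_animal_day(raw, seed=stage_seed(seed, "subsample:recovery"))
    polygon = ra.kde_isopleth(used[["x", "y"]].to_numpy(), cfg.isopleth_level, dem)
    parts = []
    for w in winters:
        uw = used[used["winter"] == w].copy()
        uw["month"] = [_key(w, m) for m in uw["month"]]
        snow_keyed = {_key(w, m): r for m, r in snows[w].items()}
        parts.append(
            rsf.build_design(
                uw, polygon, snow_keyed, canopy, dist, floor,
                seed=stage_seed(seed, f"available:recovery:{w}"),
            )
        )
    design = pd.concat(parts, ignore_index=True)
    model = rsf.fit_rsf(design, strata="month")
    truth_map = {
        "cc": truth.beta_cc, "sd": truth.beta_sd,
        "prox": truth.beta_prox, "inter": truth.beta_inter,
    }
    z = {k: (model.beta[k] - truth_map[k]) / model.se[k] for k in model.beta}
    return {
        "truth": truth, "model": model, "design": design, "polygon": polygon,
        "z": z, "used": used, "covariates": {
            _key(w, m): {"cc": canopy, "sd": snows[w][m], "dist": dist}
            for w in winters for m in cfg.months
        },
    }


# ----------------------------------------------------------------------
# artifact writing

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_artifacts(result: ExperimentResult, workdir: Path) -> dict:
    """Write rasters, tables and models to workdir; return the manifest."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    entries = []

    def _add(path: Path, stage: str):
        entries.append(
            {"file": str(path.relative_to(workdir)), "stage": stage, "sha256": _sha256(path)}
        )

    result.dem.write_ascii(workdir / "dem.asc")
    _add(workdir / "dem.asc", "landscape")
    result.canopy.write_ascii(workdir / "canopy.asc")
    _add(workdir / "canopy.asc", "landscape")

    for name, pts in result.sites.items():
        p = workdir / f"sites_{name}.csv"
        pd.DataFrame(pts, columns=["x", "y"]).assign(period=name).to_csv(p, index=False)
        _add(p, "sites")
        rp = workdir / f"dist_fs_{name}.asc"
        result.dist_fs[name].write_ascii(rp)
        _add(rp, "distance")

    for name, df in result.relocations.items():
        p = workdir / f"relocations_{name}.csv"
        df.to_csv(p, index=False)
        _add(p, "telemetry")
        d = workdir / f"design_{name}.csv"
        result.designs[name].to_csv(d, index=False)
        _add(d, "design")

    for name, model in result.models.items():
        p = workdir / f"model_{name}.yaml"
        payload = model.to_dict()
        payload["master_seed"] = cfg.master_seed
        p.write_text(yaml.safe_dump(payload, sort_keys=True))
        _add(p, "fit")

    rpdir = workdir / "rp"
    rpdir.mkdir(exist_ok=True)
    for (label, winter, month), rp in result.rp_maps.items():
        p = rpdir / f"rp_{label}_{winter}_{month}.asc"
        rp.raster.write_ascii(p)
        _add(p, "predict")

    kp = workdir / "kappas.csv"
    result.kappa_frame().to_csv(kp, index=False)
    _add(kp, "compare")

    rows = []
    for month, res in result.anova.items():
        for _, r in res["tukey"].iterrows():
            rows.append(
                {
                    "month": month, "anova_F": res["anova_F"], "anova_p": res["anova_p"],
                    "group1": r["group1"], "group2": r["group2"],
                    "p_adj": r["p_adj"], "stars": r["stars"],
                }
            )
    ap = workdir / "anova.csv"
    pd.DataFrame(rows).to_csv(ap, index=False)
    _add(ap, "compare")

    vp = workdir / "validation.yaml"
    vp.write_text(
        yaml.safe_dump(
            {
                name: {
                    "auc": float(v["auc"]),
                    "mean_tau": float(v["kfold"].mean_tau),
                    "per_fold_tau": [float(t) for t in v["kfold"].per_fold_tau],
                    "per_fold_p": [float(t) for t in v["kfold"].per_fold_p],
                }
                for name, v in result.validation.items()
            },
            sort_keys=True,
        )
    )
    _add(vp, "validate")

    subdir = workdir / "subtraction"
    subdir.mkdir(exist_ok=True)
    for (month, later, earlier), grid in result.subtraction.items():
        p = subdir / f"diff_{month}_{later.replace(':', '-')}_minus_{earlier.replace(':', '-')}.asc"
        grid.write_ascii(p)
        _add(p, "subtract")

    manifest = {
        "master_seed": cfg.master_seed,
        "months": list(cfg.months),
        "artifacts": entries,
    }
    (workdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def plot_duration_by_elevation(result: ExperimentResult, path) -> None:
    """Diagnostic figure: snow-cover-duration quartiles vs. elevation per regime."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    labels = sorted({k[0] for k in result.snow_cover})
    for label in labels:
        winters = [w for (lb, w) in result.snow_cover if lb == label]
        stacks = [result.snow_cover[(label, w)].values for w in winters]
        mean_cover = result.dem.like(np.mean(stacks, axis=0))
        table = ra.duration_by_elevation(mean_cover, result.dem, band_width_m=200.0)
        ax.plot(table["elev_lo"], table["p50"], label=label)
        ax.fill_between(table["elev_lo"], table["p25"], table["p75"], alpha=0.2)
    ax.set_xlabel("elevation band (m)")
    ax.set_ylabel("snow cover duration (days > 5 cm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
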