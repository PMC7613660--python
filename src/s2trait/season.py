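"""Synthetic irrigated-wheat season with recoverable ground truth.

Generates a full season of an irrigated winter-wheat campaign: per-ESU
trait trajectories (double-logistic LAI phenology, near-constant leaf
chlorophyll declining in senescence, a canopy-tracking water curve with
irrigation steps), a per-date stack of 10-band reflectance scenes rendered
with the same forward surrogate used for training, and a field-campaign
table with measurement noise.  Because every quantity derives from known
parameters, each pipeline stage has a recoverable truth to validate
against.

Within-paddock spatial variability is a smooth multiplicative field
interpolating per-ESU lognormal factors (coefficient of variation
``esu_cv``), so ESU records are exactly consistent with the pixels under
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .al import al_loop
from .config import PipelineConfig
from .gpr import GaussianProcessTraitRegressor
from .insitu import CAMPAIGN_COLUMNS
from .mapping import apply_model, compute_metrics, extract_timeseries
from .raster import Affine, RasterStack
from .rtm import (
    TABLE1_RANGES,
    TrainingSet,
    _surrogate_reflectance,
    augment_nonvegetated,
    build_training_db,
    simulate_fvc,
)

__all__ = ["SeasonConfig", "SeasonTruth", "trait_trajectories",
           "generate_season", "render_scenes", "recovery_experiment",
           "RECOVERY_R2_THRESHOLDS"]

TRAITS = ("lai", "ccc", "vwc")

# Held-out parameter-recovery pass levels for the three traits at the
# default 2% reflectance noise.
RECOVERY_R2_THRESHOLDS = {"lai": 0.90, "ccc": 0.80, "vwc": 0.70}

DEFAULT_SCENE_DATES = (
    "2020-08-29", "2020-09-18", "2020-09-28", "2020-10-13",
    "2020-11-02", "2020-11-17", "2020-12-01", "2020-12-22",
)


@dataclass
class SeasonConfig:
    """Parameters of the synthetic campaign (defaults emulate an irrigated
    winter-wheat season sown late June, peaking mid November)."""

    n_paddocks: int = 3
    esus_per_paddock: int = 3
    scene_dates: tuple[str, ...] = DEFAULT_SCENE_DATES
    sowing_date: str = "2020-06-25"
    grid_size: int = 60
    pixel_size: float = 10.0        # [m]
    # Double-logistic LAI phenology (days since sowing).
    lai_amplitude: float = 5.0      # [m2 m-2], within the design LAI range
    greenup_mid: float = 95.0       # [d]
    greenup_rate: float = 0.065     # [d-1]
    senesc_mid: float = 170.0       # [d]
    senesc_rate: float = 0.15       # [d-1]
    # Leaf chlorophyll: plateau through greenness, then declining.
    cab_plateau: float = 42.0       # [ug cm-2]
    cab_senescence_drop: float = 0.6   # fraction of plateau lost
    # Water curve: canopy-tracking EWT with irrigation steps.
    ewt_base: float = 0.006         # [cm]
    ewt_max: float = 0.028          # [cm]
    ewt_senescence_drop: float = 0.5
    irrigation_dates: tuple[str, ...] = ("2020-09-17", "2020-11-17")
    irrigation_step: float = 0.002  # [cm] added per irrigation
    alia: float = 55.0              # [deg]
    soil_brightness: float = 0.35
    reflectance_noise: float = 0.02   # relative SD, multiplicative
    esu_cv: float = 0.10            # between-ESU lognormal CV
    measurement_cv: float = 0.05    # field instrument relative noise
    seed: int = 0

    def __post_init__(self):
        lo, hi = TABLE1_RANGES["LAI"]
        if not lo <= self.lai_amplitude <= hi:
            raise ValueError(
                f"lai_amplitude {self.lai_amplitude} outside design range "
                f"[{lo}, {hi}]"
            )
        t = [pd.Timestamp(d) for d in self.scene_dates]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("scene_dates must be strictly increasing")
        if self.senesc_mid <= self.greenup_mid:
            raise ValueError("senescence must follow green-up")

    def days_since_sowing(self, dates=None) -> np.ndarray:
        t0 = pd.Timestamp(self.sowing_date)
        dates = self.scene_dates if dates is None else dates
        return np.array([(pd.Timestamp(d) - t0).days for d in dates],
                        dtype=float)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lai_curve(cfg: SeasonConfig, t: np.ndarray) -> np.ndarray:
    lai = cfg.lai_amplitude * (
        _sigmoid(cfg.greenup_rate * (t - cfg.greenup_mid))
        - _sigmoid(cfg.senesc_rate * (t - cfg.senesc_mid))
    )
    if np.any(lai < 0):
        raise ValueError("curve parameters produce negative LAI")
    return lai


def _cab_curve(cfg: SeasonConfig, t: np.ndarray) -> np.ndarray:
    sen = _sigmoid(cfg.senesc_rate * (t - cfg.senesc_mid))
    return cfg.cab_plateau * (1.0 - cfg.cab_senescence_drop * sen)


def _ewt_curve(cfg: SeasonConfig, t: np.ndarray) -> np.ndarray:
    canopy = _sigmoid(cfg.greenup_rate * (t - cfg.greenup_mid))
    sen = _sigmoid(cfg.senesc_rate * (t - cfg.senesc_mid))
    ewt = cfg.ewt_base + (cfg.ewt_max - cfg.ewt_base) * canopy
    t_irr = cfg.days_since_sowing(cfg.irrigation_dates)
    for ti in t_irr:
        ewt = ewt + cfg.irrigation_step * (t >= ti)
    return ewt * (1.0 - cfg.ewt_senescence_drop * sen)


def _paddock_layout(cfg: SeasonConfig):
    """Rectangular paddocks with ESU pixels inside; raises if the grid is
    too small for the layout."""
    n = cfg.grid_size
    size = 14
    margin = 6
    stride = size + 4
    if n < margin + cfg.n_paddocks * stride - 4:
        raise ValueError(
            f"grid_size {n} too small for {cfg.n_paddocks} paddocks"
        )
    paddocks = []
    for p in range(cfg.n_paddocks):
        r0, c0 = 8, margin + p * stride
        esus = [(r0 + 3 + 5 * e, c0 + 3 + 4 * e)
                for e in range(cfg.esus_per_paddock)]
        paddocks.append({"id": f"P{p + 1}", "rows": (r0, r0 + size),
                         "cols": (c0, c0 + size), "esus": esus})
    return paddocks


def _factor_field(cfg: SeasonConfig, paddock, g_factors, shape):
    """Smooth multiplicative field interpolating per-ESU lognormal factors
    with Gaussian bumps (width 3 px) plus a weak unit baseline."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    tau2 = 2.0 * 3.0 ** 2
    wsum = np.full(shape, 0.2)          # baseline weight toward factor 1
    fsum = np.full(shape, 0.2)
    for (er, ec), g in zip(paddock["esus"], g_factors):
        w = np.exp(-((rr - er) ** 2 + (cc - ec) ** 2) / tau2)
        wsum += w
        fsum += w * g
    return fsum / wsum


@dataclass
class SeasonTruth:
    """Ground truth plus rendered scenes and a noisy campaign table."""

    config: SeasonConfig
    records: pd.DataFrame          # per (date, esu): true traits + position
    scenes: list[RasterStack]
    campaign: pd.DataFrame         # campaign-CSV-shaped measured table
    paddocks: list[dict]
    esu_points: dict               # esu_id -> (x, y)

    def campaign_csv(self, path: str | Path) -> None:
        self.campaign.to_csv(Path(path), index=False)

    def paddock_geojson(self) -> dict:
        """Paddock footprints as a GeoJSON FeatureCollection (stack CRS)."""
        features = []
        t = self.scenes[0].transform
        for p in self.paddocks:
            (r0, r1), (c0, c1) = p["rows"], p["cols"]
            x0, y0 = t.xy(r0, c0, center=False)
            x1, y1 = t.xy(r1, c1, center=False)
            ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
            features.append({
                "type": "Feature",
                "properties": {"paddock_id": p["id"]},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
        return {"type": "FeatureCollection", "features": features}


def trait_trajectories(cfg: SeasonConfig) -> pd.DataFrame:
    """Per-date, per-ESU true trait values (LAI, Cab, EWT, FVC, CCC, VWC).

    The derived truths satisfy the canopy upscalings exactly:
    CCC = Cab*LAI/100 and VWC = EWT*LAI*FVC*1e4.
    """
    rng = np.random.default_rng(cfg.seed)
    paddocks = _paddock_layout(cfg)
    t = cfg.days_since_sowing()
    lai_t = _lai_curve(cfg, t)
    cab_t = _cab_curve(cfg, t)
    ewt_t = _ewt_curve(cfg, t)
    sigma = np.sqrt(np.log1p(cfg.esu_cv ** 2))
    rows = []
    for p in paddocks:
        n_esu = len(p["esus"])
        g = (np.exp(rng.normal(-0.5 * sigma ** 2, sigma, n_esu))
             if cfg.esu_cv > 0 else np.ones(n_esu))
        for e, ((er, ec), ge) in enumerate(zip(p["esus"], g)):
            lai = np.minimum(lai_t * ge, TABLE1_RANGES["LAI"][1])
            cab = np.clip(cab_t * ge ** 0.25, 1.0, TABLE1_RANGES["Cab"][1])
            ewt = np.clip(ewt_t * ge ** 0.5, TABLE1_RANGES["EWT"][0],
                          TABLE1_RANGES["EWT"][1])
            fvc = simulate_fvc(lai, cfg.alia)
            for i, d in enumerate(cfg.scene_dates):
                rows.append({
                    "date": d, "paddock_id": p["id"],
                    "esu_id": f"{p['id']}-E{e + 1}",
                    "row": er, "col": ec, "factor": ge,
                    "lai": lai[i], "cab": cab[i], "ewt": ewt[i],
                    "fvc": fvc[i],
                    "ccc": cab[i] * lai[i] / 100.0,
                    "vwc": ewt[i] * lai[i] * fvc[i] * 1e4,
                })
    return pd.DataFrame(rows)


def render_scenes(truth: pd.DataFrame, cfg: SeasonConfig) -> list[RasterStack]:
    """Rasterize the season: in-paddock pixels get forward-simulated
    reflectance of their local trait values (smooth within-paddock
    gradients), the background gets bare-soil spectra; multiplicative
    Gaussian noise with SD ``reflectance_noise``; clipped to [0, 1]."""
    paddocks = _paddock_layout(cfg)
    n = cfg.grid_size
    transform = Affine.from_origin(500000.0, 5600000.0, cfg.pixel_size)
    t = cfg.days_since_sowing()
    lai_t = _lai_curve(cfg, t)
    cab_t = _cab_curve(cfg, t)
    ewt_t = _ewt_curve(cfg, t)

    # Per-paddock factor fields from the ESU factors recorded in the truth.
    fields = []
    for p in paddocks:
        g = [truth[(truth["paddock_id"] == p["id"])
                   & (truth["row"] == er) & (truth["col"] == ec)
                   ]["factor"].iloc[0]
             for er, ec in p["esus"]]
        fields.append(_factor_field(cfg, p, g, (n, n)))

    scenes = []
    bare = _surrogate_reflectance(
        40.0, 0.02, 0.005, 0.005, 0.0, cfg.alia, cfg.soil_brightness
    )[0]
    for i, d in enumerate(cfg.scene_dates):
        cube = np.empty((10, n, n))
        cube[:] = bare[:, None, None]
        for p, f in zip(paddocks, fields):
            (r0, r1), (c0, c1) = p["rows"], p["cols"]
            fp = f[r0:r1, c0:c1]
            lai = np.minimum(lai_t[i] * fp, TABLE1_RANGES["LAI"][1]).ravel()
            cab = np.clip(cab_t[i] * fp ** 0.25, 1.0,
                          TABLE1_RANGES["Cab"][1]).ravel()
            ewt = np.clip(ewt_t[i] * fp ** 0.5, TABLE1_RANGES["EWT"][0],
                          TABLE1_RANGES["EWT"][1]).ravel()
            refl = _surrogate_reflectance(
                cab, ewt, 0.005, 0.005, lai, cfg.alia, cfg.soil_brightness
            )
            cube[:, r0:r1, c0:c1] = refl.T.reshape(10, r1 - r0, c1 - c0)
        if cfg.reflectance_noise > 0:
            rng = np.random.default_rng([cfg.seed, 1000 + i])
            cube = cube * rng.normal(1.0, cfg.reflectance_noise, cube.shape)
        cube = np.clip(cube, 0.0, 1.0)
        scenes.append(RasterStack(data=cube, transform=transform, date=d))
    return scenes


def _campaign_table(truth: pd.DataFrame, cfg: SeasonConfig) -> pd.DataFrame:
    """Render a measured campaign table from truth with multiplicative
    instrument noise (relative SD ``measurement_cv``); fresh/dry weights are
    back-computed so the in-situ formulas reproduce the noisy traits."""
    rng = np.random.default_rng([cfg.seed, 77])
    cv = cfg.measurement_cv
    m = truth.copy()

    def noisy(x, lo=0.0, hi=np.inf):
        x = np.asarray(x, dtype=float)
        return np.clip(x * rng.normal(1.0, cv, x.shape), lo, hi) if cv > 0 \
            else x

    lai_m = noisy(m["lai"])
    fvc_m = noisy(m["fvc"], 1e-3, 1.0)
    cab_m = noisy(m["cab"], 1.0)
    ewt_m = noisy(m["ewt"], 1e-5)
    vwc_m = noisy(m["vwc"])
    area = 0.02
    water = vwc_m / fvc_m * area          # FW - DW [g]
    dw = water / 3.0                      # dry matter ~ 1/4 of fresh weight
    fw = water + dw
    leaf_area = np.where(ewt_m > 0, water / ewt_m, np.nan)
    spad = np.log(np.asarray(cab_m) / 12.23) / 0.0279
    out = pd.DataFrame({
        "date": m["date"],
        "paddock_id": m["paddock_id"],
        "esu_id": m["esu_id"],
        "lai": lai_m,
        "fvc_pct": fvc_m * 100.0,
        "spad": spad,
        "cab_ugcm2": cab_m,
        "fw_g": fw,
        "dw_g": dw,
        "area_m2": area,
        "leaf_area_cm2": leaf_area,
        "zadoks": "",
    })
    return out[list(CAMPAIGN_COLUMNS)]


def generate_season(cfg: SeasonConfig | None = None) -> SeasonTruth:
    """Generate truth trajectories, rendered scenes and the campaign table."""
    cfg = cfg or SeasonConfig()
    truth = trait_trajectories(cfg)
    scenes = render_scenes(truth, cfg)
    campaign = _campaign_table(truth, cfg)
    paddocks = _paddock_layout(cfg)
    t = scenes[0].transform
    esu_points = {}
    for _, r in truth.drop_duplicates("esu_id").iterrows():
        x, y = t.xy(r["row"], r["col"])
        esu_points[r["esu_id"]] = (float(x), float(y))
    return SeasonTruth(config=cfg, records=truth, scenes=scenes,
                       campaign=campaign, paddocks=paddocks,
                       esu_points=esu_points)


def _esu_spectra(season: SeasonTruth, esu_ids, dates) -> pd.DataFrame:
    """Scene spectra sampled at ESU pixels for the given dates."""
    rows = []
    by_date = {s.date: s for s in season.scenes}
    recs = season.records
    for d in dates:
        stack = by_date[d]
        for esu in esu_ids:
            r = recs[(recs["date"] == d) & (recs["esu_id"] == esu)].iloc[0]
            spec = stack.data[:, int(r["row"]), int(r["col"])]
            rows.append({"date": d, "esu_id": esu, "spectrum": spec,
                         "lai": r["lai"], "ccc": r["ccc"], "vwc": r["vwc"]})
    return pd.DataFrame(rows)


def recovery_experiment(
    cfg: SeasonConfig | None = None,
    pipeline: PipelineConfig | None = None,
) -> dict:
    """End-to-end parameter recovery on the synthetic season.

    Builds the simulated pool, augments it, runs EBD active learning per
    trait against measured (noisy) ESU samples from two of the three ESUs
    per paddock, then evaluates the optimized models against the *true*
    traits of the held-out ESUs, maps the peak-greenness scene, and extracts
    the ESU time series.

    Returns a report dict with per-trait metrics, AL trajectories,
    uncertainty summaries and pass/fail against the recovery thresholds.
    """
    cfg = cfg or SeasonConfig()
    pipeline = pipeline or PipelineConfig()
    season = generate_season(cfg)

    ts = build_training_db(
        n=pipeline.training.n, seed=pipeline.training.seed,
        backend=pipeline.training.backend, ranges=pipeline.training.ranges,
    )
    ts = augment_nonvegetated(
        ts, n_bare=pipeline.training.n_bare,
        n_senescent=pipeline.training.n_senescent,
        seed=pipeline.training.seed,
    )

    # Greenness period: dates before the senescence midpoint.
    t = cfg.days_since_sowing()
    green_dates = [d for d, ti in zip(cfg.scene_dates, t)
                   if ti < cfg.senesc_mid]
    esu_ids = sorted(season.esu_points)
    val_esus = [e for e in esu_ids if not e.endswith(f"E{cfg.esus_per_paddock}")]
    held_esus = [e for e in esu_ids if e.endswith(f"E{cfg.esus_per_paddock}")]

    # AL validation uses measured (noisy) labels, as a field campaign would.
    camp = season.campaign.set_index(["date", "esu_id"])
    val = _esu_spectra(season, val_esus, green_dates)
    X_val = np.vstack(val["spectrum"].to_numpy())
    held = _esu_spectra(season, held_esus, green_dates)
    X_held = np.vstack(held["spectrum"].to_numpy())

    def measured(trait, frame):
        if trait == "lai":
            return np.array([camp.loc[(d, e), "lai"]
                             for d, e in zip(frame["date"], frame["esu_id"])])
        if trait == "ccc":
            return np.array([
                camp.loc[(d, e), "cab_ugcm2"] * camp.loc[(d, e), "lai"] / 100.0
                for d, e in zip(frame["date"], frame["esu_id"])])
        fvc = np.array([camp.loc[(d, e), "fvc_pct"]
                        for d, e in zip(frame["date"], frame["esu_id"])]) / 100
        wh = np.array([
            (camp.loc[(d, e), "fw_g"] - camp.loc[(d, e), "dw_g"]) /
            camp.loc[(d, e), "area_m2"]
            for d, e in zip(frame["date"], frame["esu_id"])])
        return wh * fvc

    al_cfg = {"n_init": pipeline.al.n_init, "max_iter": pipeline.al.max_iter,
              "hyp_refresh": pipeline.al.hyp_refresh}
    gpr_cfg = {"n_restarts": pipeline.gpr.n_restarts, "ard": pipeline.gpr.ard,
               "max_opt_iter": pipeline.gpr.max_opt_iter}

    peak_idx = int(np.argmax(_lai_curve(cfg, t)))
    peak_scene = season.scenes[peak_idx]
    mask = season.paddock_geojson()
    report = {"traits": {}, "thresholds": dict(RECOVERY_R2_THRESHOLDS),
              "passed": {}, "dates": {"greenness": green_dates,
                                      "peak": cfg.scene_dates[peak_idx]},
              "n_training_pool": len(ts)}

    for trait in TRAITS:
        y_val = measured(trait, val)
        model, state = al_loop(
            ts, (X_val, y_val), trait,
            config={**al_cfg, "gpr_params": gpr_cfg}, seed=cfg.seed,
        )
        # Initial 10-sample model for the uncertainty-shrink comparison.
        init_idx = state.train_indices[:pipeline.al.n_init]
        init_model = GaussianProcessTraitRegressor(
            **gpr_cfg, random_state=cfg.seed, trait_name=trait,
        ).fit(ts.spectra[init_idx], ts.labels(trait)[init_idx])

        y_true = held[trait].to_numpy(float)
        pred, sd = model.predict(X_held, return_std=True)
        metrics = compute_metrics(y_true, pred)

        tmap = apply_model(model, peak_scene, mask_geoms=mask,
                           clip_negative=pipeline.mapping.clip_negative)
        tmap_init = apply_model(init_model, peak_scene, mask_geoms=mask,
                                clip_negative=pipeline.mapping.clip_negative)
        maps = [apply_model(model, s, mask_geoms=mask) for s in season.scenes]
        _, per_date = extract_timeseries(maps, season.esu_points)

        report["traits"][trait] = {
            "metrics": metrics.as_dict(),
            "n_selected": len(state.train_indices),
            "n_accepted": len(state.train_indices) - pipeline.al.n_init,
            "n_iterations": len(state.history),
            "rmse_initial": state.rmse_trajectory[0],
            "rmse_final": state.rmse_trajectory[-1],
            "rmse_trajectory": list(state.rmse_trajectory),
            "r2_trajectory": list(state.r2_trajectory),
            "mean_map_sd_final": float(np.mean(tmap.sd[tmap.mask])),
            "mean_map_sd_initial": float(np.mean(tmap_init.sd[tmap_init.mask])),
            "timeseries": per_date.to_dict(orient="list"),
        }
        report["passed"][trait] = bool(
            metrics.r2 >= RECOVERY_R2_THRESHOLDS[trait]
        )
    return report
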