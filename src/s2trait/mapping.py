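"""Per-pixel model application, time-series extraction and goodness-of-fit.

Every valid pixel of a reflectance stack is pushed through the trained GP,
producing a trait mean layer and an SD layer (observation-level
uncertainty).  Negative trait predictions are clipped at zero (traits are
non-negative; the clip count is logged and stored in the map).  Point time
series use nearest-pixel sampling since elementary sampling units were
sized to a single 10 m pixel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as geojson_shape

from .raster import RasterStack, TraitMap

__all__ = [
    "Metrics",
    "apply_model",
    "extract_timeseries",
    "compute_metrics",
    "scatter_validation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Metrics:
    """Standard regression goodness-of-fit summary.

    nrmse is normalized by the observed range; mape is computed over
    non-zero observations only; r2 is NaN for constant observations.
    """

    r2: float
    rmse: float
    nrmse: float
    mae: float
    mape: float
    n: int

    def as_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "nrmse": self.nrmse,
            "mae": self.mae, "mape": self.mape, "n": self.n,
        }


def compute_metrics(obs, pred) -> Metrics:
    """R2, RMSE, NRMSE (range-normalized), MAE and MAPE [%]."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty input")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err ** 2)) / sstot if sstot > 0 else math.nan
    rng = float(obs.max() - obs.min())
    nrmse = rmse / rng if rng > 0 else math.nan
    nz = obs != 0
    mape = (float(100.0 * np.mean(np.abs(err[nz] / obs[nz])))
            if np.any(nz) else math.nan)
    return Metrics(r2=r2, rmse=rmse, nrmse=nrmse, mae=mae, mape=mape,
                   n=int(obs.size))


def _as_geometry(mask_geoms):
    """Accept a shapely geometry, a GeoJSON mapping, or a list of either."""
    if mask_geoms is None:
        return None
    if isinstance(mask_geoms, dict):
        if mask_geoms.get("type") == "FeatureCollection":
            geoms = [geojson_shape(f["geometry"])
                     for f in mask_geoms["features"]]
        elif mask_geoms.get("type") == "Feature":
            geoms = [geojson_shape(mask_geoms["geometry"])]
        else:
            geoms = [geojson_shape(mask_geoms)]
    elif isinstance(mask_geoms, (list, tuple)):
        geoms = [g if hasattr(g, "geom_type") else geojson_shape(g)
                 for g in mask_geoms]
    else:
        geoms = [mask_geoms]
    return shapely.union_all(geoms)


def apply_model(model, stack: RasterStack, mask_geoms=None,
                clip_negative: bool = True) -> TraitMap:
    """Predict a trait map (mean + SD) from a reflectance stack.

    Pixels equal to nodata, outside [0, 1], or outside ``mask_geoms`` (any
    GeoJSON-like polygons in the stack CRS) are invalid and carry nodata.
    """
    if stack.data.shape[0] != model.n_features_in_:
        raise ValueError(
            f"band count mismatch: stack has {stack.data.shape[0]}, "
            f"model expects {model.n_features_in_}"
        )
    rows, cols = stack.shape
    valid = stack.valid_mask()
    geom = _as_geometry(mask_geoms)
    if geom is not None:
        rr, cc = np.mgrid[0:rows, 0:cols]
        x, y = stack.transform.xy(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(geom, x, y).reshape(rows, cols)
        valid &= inside
    mean = np.full((rows, cols), stack.nodata, dtype=float)
    sd = np.full((rows, cols), stack.nodata, dtype=float)
    clip_count = 0
    if valid.any():
        X = stack.data[:, valid].T
        mu, s = model.predict(X, return_std=True)
        if clip_negative:
            clip_count = int(np.sum(mu < 0))
            mu = np.maximum(mu, 0.0)
        mean[valid] = mu
        sd[valid] = s
    if clip_count:
        logger.info(
            "apply_model(%s, date=%s): clipped %d negative predictions",
            model.trait_name, stack.date, clip_count,
        )
    return TraitMap(
        mean=mean, sd=sd, mask=valid,
        trait_name=model.trait_name or "trait",
        transform=stack.transform, crs=stack.crs, date=stack.date,
        nodata=stack.nodata, clip_count=clip_count,
    )


def extract_timeseries(maps, points) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nearest-pixel trait time series at georeferenced points.

    Parameters
    ----------
    maps : list of TraitMap
    points : dict point_id -> (x, y), or list of (x, y)

    Returns
    -------
    per_point : DataFrame (date, point_id, mean, sd, valid)
    per_date : DataFrame (date, mean, sd_across_points, n_valid)
        Across-point mean and SD per date.
    """
    if not isinstance(points, dict):
        points = {i: p for i, p in enumerate(points)}
    rows = []
    for m in maps:
        nr, nc = m.mean.shape
        for pid, (x, y) in points.items():
            r, c = m.transform.rowcol(x, y)
            if not (0 <= r < nr and 0 <= c < nc):
                rows.append({"date": m.date, "point_id": pid,
                             "mean": math.nan, "sd": math.nan,
                             "valid": False, "in_extent": False})
                continue
            ok = bool(m.mask[r, c])
            rows.append({
                "date": m.date,
                "point_id": pid,
                "mean": float(m.mean[r, c]) if ok else math.nan,
                "sd": float(m.sd[r, c]) if ok else math.nan,
                "valid": ok,
                "in_extent": True,
            })
    per_point = pd.DataFrame(rows)
    g = per_point[per_point["valid"]].groupby("date")["mean"]
    per_date = g.agg(mean="mean", sd_across_points="std", n_valid="count")
    per_date = per_date.reset_index()
    return per_point, per_date


def scatter_validation(model, X_val, y_val) -> tuple[pd.DataFrame, Metrics]:
    """Per-sample predictions with SD plus summary metrics, exportable for
    observed-vs-estimated 1:1 plots."""
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    pred, sd = model.predict(X_val, return_std=True)
    table = pd.DataFrame({"obs": y_val, "pred": pred, "sd": sd})
    return table, compute_metrics(y_val, pred)
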