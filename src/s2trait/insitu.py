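"""Field-campaign data model and in-situ trait conversion formulas.

Covers the handheld-instrument conversions and canopy upscalings used to
turn raw field measurements into the three retrievable traits:

* SPAD reading -> leaf chlorophyll: ``Cab = 12.23 * exp(0.0279 * SPAD)``
  [ug cm-2];
* canopy chlorophyll: ``CCC = Cab * LAI / 100`` [g m-2];
* leaf equivalent water thickness: ``EWT = (FW - DW) / Al`` [g cm-2];
* canopy water content: ``CWC = EWT * LAI * 1e4`` [g m-2];
* homogeneous vegetation water content: ``VWC_h = (FW - DW) / A`` [g m-2];
* cover-corrected water content: ``VWC = VWC_h * FVC`` [g m-2].

FVC is stored internally as a fraction; campaign CSVs carry it as percent
(`fvc_pct` column, field convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "spad_to_cab",
    "ccc_insitu",
    "ewt_leaf",
    "cwc",
    "vwc_h",
    "vwc",
    "ESURecord",
    "CampaignDB",
    "load_campaign",
    "match_to_acquisitions",
    "CAMPAIGN_COLUMNS",
]

#: Default destructive sampling area [m2] (a sowing-track cut).
DEFAULT_SAMPLING_AREA_M2 = 0.02

CAMPAIGN_COLUMNS = (
    "date", "paddock_id", "esu_id", "lai", "fvc_pct", "spad", "cab_ugcm2",
    "fw_g", "dw_g", "area_m2", "leaf_area_cm2", "zadoks",
)
_REQUIRED_COLUMNS = ("date", "paddock_id", "esu_id", "lai", "fvc_pct",
                     "fw_g", "dw_g")


def spad_to_cab(spad):
    """Leaf chlorophyll a+b [ug cm-2] from a SPAD-502 reading."""
    spad = np.asarray(spad, dtype=float)
    if np.any(spad < 0):
        raise ValueError("SPAD readings must be non-negative")
    out = 12.23 * np.exp(0.0279 * spad)
    return float(out) if out.ndim == 0 else out


def ccc_insitu(cab, lai):
    """Canopy chlorophyll content [g m-2]: Cab upscaled by LAI.

    The factor 100 converts from leaf-level ug cm-2 to canopy-level g m-2.
    """
    cab = np.asarray(cab, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(cab < 0) or np.any(lai < 0):
        raise ValueError("cab and lai must be non-negative")
    out = cab * lai / 100.0
    return float(out) if out.ndim == 0 else out


def ewt_leaf(fw, dw, leaf_area):
    """Equivalent water thickness [g cm-2] from fresh/dry weight [g] and
    leaf area [cm2]."""
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    leaf_area = np.asarray(leaf_area, dtype=float)
    if np.any(dw > fw):
        raise ValueError("dry weight exceeds fresh weight")
    if np.any(leaf_area <= 0):
        raise ValueError("leaf area must be positive")
    out = (fw - dw) / leaf_area
    return float(out) if out.ndim == 0 else out


def cwc(ewt, lai):
    """Canopy water content [g m-2] = EWT [g cm-2] x LAI, with the 1e4
    factor converting leaf-level per-cm2 mass to per-m2 ground area."""
    ewt = np.asarray(ewt, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(ewt < 0) or np.any(lai < 0):
        raise ValueError("ewt and lai must be non-negative")
    out = ewt * lai * 1e4
    return float(out) if out.ndim == 0 else out


def vwc_h(fw, dw, area):
    """Vegetation water content [g m-2] assuming a homogeneously covered
    square meter: (FW - DW) / A."""
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(dw > fw):
        raise ValueError("dry weight exceeds fresh weight")
    if np.any(area <= 0):
        raise ValueError("sampling area must be positive")
    out = (fw - dw) / area
    return float(out) if out.ndim == 0 else out


def vwc(fw, dw, area, fvc):
    """Cover-corrected vegetation water content [g m-2]: VWC_h x FVC."""
    fvc = np.asarray(fvc, dtype=float)
    if np.any((fvc < 0) | (fvc > 1)):
        raise ValueError("fvc must be a fraction in [0, 1]")
    out = vwc_h(fw, dw, area) * fvc
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class ESURecord:
    """One elementary-sampling-unit visit (a 10 m x 10 m plot on one date)."""

    date: Date
    paddock_id: str
    esu_id: str
    lai: float                       # [m2 m-2]
    fvc: float                       # fraction
    fw: float                        # fresh weight [g]
    dw: float                        # dry weight [g]
    area: float = DEFAULT_SAMPLING_AREA_M2   # sampling area [m2]
    spad: float | None = None
    cab: float | None = None         # [ug cm-2], derived from spad if absent
    leaf_area: float | None = None   # Al [cm2]
    zadoks: str | None = None

    def __post_init__(self):
        if self.dw > self.fw:
            raise ValueError(
                f"ESU {self.esu_id} {self.date}: dry weight {self.dw} "
                f"exceeds fresh weight {self.fw}"
            )
        if not 0.0 <= self.fvc <= 1.0:
            raise ValueError(f"fvc must be in [0, 1], got {self.fvc}")
        if self.lai < 0:
            raise ValueError("lai must be non-negative")
        if self.area <= 0:
            raise ValueError("sampling area must be positive")
        if self.cab is None and self.spad is not None:
            self.cab = spad_to_cab(self.spad)


class CampaignDB:
    """Per-date, per-ESU in-situ records with derived trait columns."""

    def __init__(self, records: list[ESURecord]):
        self.records = records
        self.frame = self._derive()

    def __len__(self) -> int:
        return len(self.records)

    def _derive(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            ccc_v = ccc_insitu(r.cab, r.lai) if r.cab is not None else math.nan
            ewt_v = (ewt_leaf(r.fw, r.dw, r.leaf_area)
                     if r.leaf_area else math.nan)
            rows.append({
                "date": pd.Timestamp(r.date),
                "paddock_id": r.paddock_id,
                "esu_id": r.esu_id,
                "lai": r.lai,
                "fvc": r.fvc,
                "spad": r.spad,
                "cab": r.cab,
                "fw": r.fw,
                "dw": r.dw,
                "area": r.area,
                "leaf_area": r.leaf_area,
                "zadoks": r.zadoks,
                "ccc": ccc_v,
                "ewt": ewt_v,
                "cwc": cwc(ewt_v, r.lai) if not math.isnan(ewt_v) else math.nan,
                "vwc_h": vwc_h(r.fw, r.dw, r.area),
                "vwc": vwc(r.fw, r.dw, r.area, r.fvc),
            })
        return pd.DataFrame(rows)

    def date_stats(self, column: str) -> pd.DataFrame:
        """Per-date mean/SD/min/max of a derived column (per-ESU values are
        derived first, then aggregated by date)."""
        g = self.frame.groupby("date")[column]
        return g.agg(["mean", "std", "min", "max"])


def load_campaign(path: str | Path) -> CampaignDB:
    """Parse a campaign CSV into a :class:`CampaignDB`.

    Expected columns: ``date,paddock_id,esu_id,lai,fvc_pct,spad,cab_ugcm2,
    fw_g,dw_g,area_m2,leaf_area_cm2,zadoks`` (ISO-8601 dates; optional cells
    may be empty).  Percent FVC is converted to a fraction.  Rows violating
    invariants are rejected with their row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"campaign CSV not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"campaign CSV missing required columns: {missing}")
    records = []
    errors = []
    for i, row in df.iterrows():
        try:
            d = pd.Timestamp(row["date"]).date()
        except (ValueError, TypeError):
            errors.append(f"row {i}: unparseable date {row['date']!r}")
            continue
        try:
            records.append(ESURecord(
                date=d,
                paddock_id=str(row["paddock_id"]),
                esu_id=str(row["esu_id"]),
                lai=float(row["lai"]),
                fvc=float(row["fvc_pct"]) / 100.0,
                fw=float(row["fw_g"]),
                dw=float(row["dw_g"]),
                area=(float(row["area_m2"])
                      if "area_m2" in df.columns and pd.notna(row.get("area_m2"))
                      else DEFAULT_SAMPLING_AREA_M2),
                spad=(float(row["spad"])
                      if "spad" in df.columns and pd.notna(row.get("spad"))
                      else None),
                cab=(float(row["cab_ugcm2"])
                     if "cab_ugcm2" in df.columns
                     and pd.notna(row.get("cab_ugcm2")) else None),
                leaf_area=(float(row["leaf_area_cm2"])
                           if "leaf_area_cm2" in df.columns
                           and pd.notna(row.get("leaf_area_cm2")) else None),
                zadoks=(str(row["zadoks"])
                        if "zadoks" in df.columns and pd.notna(row.get("zadoks"))
                        else None),
            ))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("invalid campaign rows:\n" + "\n".join(errors))
    return CampaignDB(records)


def match_to_acquisitions(
    field_dates,
    scene_dates,
    window_days: int = 6,
) -> pd.DataFrame:
    """Pair each field date with the nearest scene date within a +/- window.

    Ties in absolute offset break to the earlier scene.  Unmatched dates get
    NaT / NaN entries.  Returns columns ``field_date, scene_date,
    delta_days`` with ``delta = scene - field`` in days.
    """
    if window_days < 0:
        raise ValueError("window_days must be non-negative")
    if hasattr(field_dates, "frame"):  # CampaignDB
        field_dates = field_dates.frame["date"].unique()
    fd = sorted(pd.Timestamp(d) for d in field_dates)
    sd = sorted(pd.Timestamp(d) for d in scene_dates)
    rows = []
    for f in fd:
        best = None
        for s in sd:  # sorted ascending: earlier scene wins exact ties
            delta = (s - f).days
            if abs(delta) <= window_days:
                if best is None or abs(delta) < abs(best[1]):
                    best = (s, delta)
        rows.append({
            "field_date": f,
            "scene_date": best[0] if best else pd.NaT,
            "delta_days": best[1] if best else np.nan,
        })
    return pd.DataFrame(rows)
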