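"""Georeferenced raster containers and TIFF + JSON-sidecar persistence.

A :class:`RasterStack` holds a 10-band reflectance cube; a :class:`TraitMap`
holds the per-pixel trait mean and predictive SD produced by a model.  Data
are written as plain multiband TIFF with the affine transform, CRS, band
names, dates and nodata value in a ``<file>.json`` sidecar, so outputs stay
self-describing without a GDAL dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import tifffile

from ._surrogate import BAND_CENTERS_NM, N_BANDS

__all__ = ["Affine", "RasterStack", "TraitMap", "DEFAULT_NODATA"]

DEFAULT_NODATA = -9999.0


class Affine(NamedTuple):
    """Row-major affine georeference: ``x = a*col + b*row + c``,
    ``y = d*col + e*row + f`` (GDAL-style, pixel upper-left anchored)."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def xy(self, row, col, center: bool = True):
        """Map (row, col) indices to world (x, y); pixel centers by default."""
        off = 0.5 if center else 0.0
        col = np.asarray(col, dtype=float) + off
        row = np.asarray(row, dtype=float) + off
        return self.a * col + self.b * row + self.c, \
            self.d * col + self.e * row + self.f

    def rowcol(self, x, y):
        """Inverse map world (x, y) to integer (row, col) indices."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("singular affine transform")
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        col = (self.e * x - self.b * y) / det
        row = (-self.d * x + self.a * y) / det
        return np.floor(row).astype(int), np.floor(col).astype(int)

    @classmethod
    def from_origin(cls, west: float, north: float, pixel: float) -> "Affine":
        """North-up grid with square pixels of size ``pixel`` [m]."""
        return cls(pixel, 0.0, west, 0.0, -pixel, north)


@dataclass
class RasterStack:
    """Reflectance cube of shape (10, rows, cols) with georeference."""

    data: np.ndarray
    transform: Affine
    crs: str = "EPSG:32720"
    nodata: float = DEFAULT_NODATA
    date: str | None = None
    band_centers_nm: np.ndarray = field(
        default_factory=lambda: BAND_CENTERS_NM.copy()
    )

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != N_BANDS:
            raise ValueError(
                f"expected ({N_BANDS}, rows, cols) cube, got {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def valid_mask(self) -> np.ndarray:
        """Pixels where every band is neither nodata nor outside [0, 1]."""
        ok = np.all(self.data != self.nodata, axis=0)
        ok &= np.all((self.data >= 0.0) & (self.data <= 1.0), axis=0)
        return ok

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.data, photometric="minisblack")
        sidecar = {
            "type": "reflectance_stack",
            "transform": list(self.transform),
            "crs": self.crs,
            "nodata": self.nodata,
            "date": self.date,
            "band_centers_nm": self.band_centers_nm.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def read(cls, path: str | Path) -> "RasterStack":
        path = Path(path)
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".json").read_text()
        )
        return cls(
            data=tifffile.imread(path),
            transform=Affine(*sidecar["transform"]),
            crs=sidecar["crs"],
            nodata=sidecar["nodata"],
            date=sidecar["date"],
            band_centers_nm=np.asarray(sidecar["band_centers_nm"]),
        )


@dataclass
class TraitMap:
    """Per-pixel trait mean and predictive SD with a valid-pixel mask."""

    mean: np.ndarray
    sd: np.ndarray
    mask: np.ndarray
    trait_name: str
    transform: Affine
    crs: str = "EPSG:32720"
    date: str | None = None
    nodata: float = DEFAULT_NODATA
    clip_count: int = 0

    def __post_init__(self):
        if not (self.mean.shape == self.sd.shape == self.mask.shape):
            raise ValueError("mean/sd/mask shapes must match")

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, np.stack([self.mean, self.sd]),
                         photometric="minisblack")
        sidecar = {
            "type": "trait_map",
            "trait_name": self.trait_name,
            "transform": list(self.transform),
            "crs": self.crs,
            "nodata": self.nodata,
            "date": self.date,
            "clip_count": self.clip_count,
            "bands": ["mean", "sd"],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def read(cls, path: str | Path) -> "TraitMap":
        path = Path(path)
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".json").read_text()
        )
        data = tifffile.imread(path)
        nodata = sidecar["nodata"]
        return cls(
            mean=data[0],
            sd=data[1],
            mask=data[0] != nodata,
            trait_name=sidecar["trait_name"],
            transform=Affine(*sidecar["transform"]),
            crs=sidecar["crs"],
            date=sidecar["date"],
            nodata=nodata,
            clip_count=sidecar.get("clip_count", 0),
        )
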