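"""Simulated training database: LHS sampling of the leaf/canopy parameter
space, forward reflectance simulation, canopy-level label derivation, and
augmentation with non-vegetated / senescent samples.

The training labels are the three retrievable traits:

* LAI   -- leaf area index [m2 m-2], passed through from the sampling;
* CCC_s -- canopy chlorophyll content, ``Cab * LAI / 100`` [g m-2];
* VWC_s -- vegetation water content, ``EWT * LAI * FVC * 1e4`` [g m-2],
  where FVC introduces the crop / bare-soil mixing.

Two forward backends are supported: the built-in analytic ``surrogate``
(coefficients in :mod:`s2trait._surrogate`) and ``prosail_pro``, an adapter
to an installed coupled leaf-canopy radiative-transfer implementation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from ._surrogate import (
    ALPHA,
    BAND_CENTERS_NM,
    BAND_NAMES,
    BETA,
    GAMMA,
    N_BANDS,
    RHO_INF,
    RHO_SOIL,
    SURROGATE_VERSION,
)

__all__ = [
    "TABLE1_RANGES",
    "FIXED_PARAMS",
    "RTMParams",
    "SpectralSample",
    "TrainingSet",
    "sample_lhs",
    "forward_reflectance",
    "simulate_fvc",
    "derive_labels",
    "build_training_db",
    "augment_nonvegetated",
]

# Free parameter ranges for the LHS design (uniform marginals).
TABLE1_RANGES: dict[str, tuple[float, float]] = {
    "Cab": (5.0, 75.0),        # leaf chlorophyll a+b [ug cm-2]
    "Nstruct": (1.0, 2.0),     # leaf structure [-]
    "Cxc": (0.0, 15.0),        # carotenoids [ug cm-2]
    "EWT": (0.0002, 0.05),     # equivalent water thickness [cm]
    "CBC": (0.001, 0.01),      # carbon-based constituents [g cm-2]
    "Canth": (0.0, 2.0),       # anthocyanins [ug cm-2]
    "Cp": (0.001, 0.0025),     # proteins [ug cm-2]
    "Cm": (0.0001, 0.03),      # leaf mass per area [ug cm-2]
    "LAI": (0.1, 7.0),         # leaf area index [m2 m-2]
    "ALIA": (30.0, 70.0),      # average leaf inclination angle [deg]
    "soil": (0.0, 1.0),        # soil brightness [-]
    "SZA": (20.0, 40.0),       # sun zenith angle [deg]
}

# Parameters held constant in the design.
FIXED_PARAMS: dict[str, float] = {
    "Cbrown": 0.0,   # brown pigment [-]
    "Hot": 0.01,     # hot spot [m m-1]
    "OZA": 0.0,      # observer zenith angle [deg]
    "DDR": 80.0,     # diffuse/direct ratio [%]
    "rAA": 0.0,      # relative azimuth angle [deg]
}

PARAM_ORDER = tuple(TABLE1_RANGES) + tuple(FIXED_PARAMS)


@dataclass(frozen=True)
class RTMParams:
    """One leaf + canopy parameter vector driving a forward simulation."""

    Cab: float
    Nstruct: float
    Cxc: float
    EWT: float
    CBC: float
    Canth: float
    Cp: float
    Cm: float
    LAI: float
    ALIA: float
    soil: float
    SZA: float
    Cbrown: float = 0.0
    Hot: float = 0.01
    OZA: float = 0.0
    DDR: float = 80.0
    rAA: float = 0.0

    def validate(self, ranges: dict[str, tuple[float, float]] | None = None) -> None:
        """Check every free field against `ranges` (default: the design
        ranges) and every fixed field against its constant."""
        ranges = TABLE1_RANGES if ranges is None else ranges
        for name, (lo, hi) in ranges.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"parameter {name}={v} outside range [{lo}, {hi}]"
                )
        for name, const in FIXED_PARAMS.items():
            if getattr(self, name) != const:
                raise ValueError(f"fixed parameter {name} must equal {const}")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SpectralSample:
    """A single 10-band reflectance spectrum."""

    reflectance: np.ndarray
    band_centers_nm: np.ndarray = field(
        default_factory=lambda: BAND_CENTERS_NM.copy()
    )

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (N_BANDS,):
            raise ValueError(f"expected {N_BANDS} bands, got shape {r.shape}")
        object.__setattr__(self, "reflectance", r)


@dataclass
class TrainingSet:
    """Paired simulated spectra and trait labels with provenance flags."""

    spectra: np.ndarray          # (n, 10)
    lai: np.ndarray              # (n,) [m2 m-2]
    ccc: np.ndarray              # (n,) [g m-2]
    vwc: np.ndarray              # (n,) [g m-2]
    fvc: np.ndarray              # (n,) fraction
    provenance: np.ndarray       # (n,) in {vegetated, bare, senescent}
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.spectra)
        for name in ("lai", "ccc", "vwc", "fvc", "provenance"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of spectra")

    def __len__(self) -> int:
        return len(self.spectra)

    def labels(self, trait: str) -> np.ndarray:
        if trait not in ("lai", "ccc", "vwc"):
            raise ValueError(f"unknown trait {trait!r}")
        return getattr(self, trait)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spectra, columns=list(BAND_NAMES))
        df["lai"] = self.lai
        df["ccc"] = self.ccc
        df["vwc"] = self.vwc
        df["fvc"] = self.fvc
        df["provenance"] = self.provenance
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write one row per sample plus a JSON sidecar with provenance
        metadata (seed, backend, ranges)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingSet":
        path = Path(path)
        df = pd.read_csv(path)
        missing = [c for c in BAND_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"training CSV missing band columns: {missing}")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            spectra=df[list(BAND_NAMES)].to_numpy(float),
            lai=df["lai"].to_numpy(float),
            ccc=df["ccc"].to_numpy(float),
            vwc=df["vwc"].to_numpy(float),
            fvc=df["fvc"].to_numpy(float),
            provenance=df["provenance"].to_numpy(str),
            meta=meta,
        )

    def concat(self, other: "TrainingSet") -> "TrainingSet":
        return TrainingSet(
            spectra=np.vstack([self.spectra, other.spectra]),
            lai=np.concatenate([self.lai, other.lai]),
            ccc=np.concatenate([self.ccc, other.ccc]),
            vwc=np.concatenate([self.vwc, other.vwc]),
            fvc=np.concatenate([self.fvc, other.fvc]),
            provenance=np.concatenate([self.provenance, other.provenance]),
            meta=dict(self.meta),
        )


def sample_lhs(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[RTMParams]:
    """Latin Hypercube sample of the free parameter space.

    Every free parameter gets exactly one sample in each of ``n`` equal-width
    strata of its range (random position within the stratum); fixed
    parameters hold their constants.  Reproducible under identical ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    ranges = TABLE1_RANGES if ranges is None else ranges
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"inverted range for parameter {name}: [{lo}, {hi}]")
    names = list(ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    lows = np.array([ranges[k][0] for k in names])
    highs = np.array([ranges[k][1] for k in names])
    scaled = qmc.scale(unit, lows, highs)
    out = []
    for row in scaled:
        kw = dict(zip(names, (float(v) for v in row)))
        out.append(RTMParams(**{**_default_free(), **kw}))
    return out


def _default_free() -> dict[str, float]:
    """Mid-range defaults for free parameters not covered by a custom range."""
    return {k: (lo + hi) / 2 for k, (lo, hi) in TABLE1_RANGES.items()}


# Broad physical bounds used to reject nonsensical forward-simulation inputs.
_PHYSICAL_BOUNDS = {
    "Cab": (0.0, 200.0),
    "EWT": (0.0, 0.5),
    "CBC": (0.0, 0.1),
    "Cm": (0.0, 0.1),
    "LAI": (0.0, 20.0),
    "ALIA": (0.0, 90.0),
    "soil": (0.0, 1.0),
    "SZA": (0.0, 90.0),
}


def _check_physical(params: RTMParams) -> None:
    for name, (lo, hi) in _PHYSICAL_BOUNDS.items():
        v = getattr(params, name)
        if not (lo <= v <= hi):
            raise ValueError(
                f"parameter {name}={v} outside physical bounds [{lo}, {hi}]"
            )


def _surrogate_reflectance(
    cab: np.ndarray,
    ewt: np.ndarray,
    cm: np.ndarray,
    cbc: np.ndarray,
    lai: np.ndarray,
    alia: np.ndarray,
    soil: np.ndarray,
) -> np.ndarray:
    """Vectorized analytic surrogate; inputs broadcast to (n,), output (n, 10)."""
    cab, ewt, cm, cbc, lai, alia, soil = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, float)) for a in (cab, ewt, cm, cbc, lai, alia, soil))
    )
    k = np.cos(np.radians(alia))
    p0 = np.exp(-k * lai)[:, None]
    dm = (cm + cbc) * 1e4
    absorb = (
        ALPHA[None, :] * cab[:, None]
        + BETA[None, :] * ewt[:, None]
        + GAMMA[None, :] * dm[:, None]
    )
    rho_leaf = RHO_INF[None, :] * np.exp(-absorb)
    refl = (1.0 - p0) * rho_leaf + p0 * soil[:, None] * RHO_SOIL[None, :]
    return np.clip(refl, 0.0, 1.0)


def _prosail_reflectance(params: RTMParams) -> np.ndarray:
    """Adapter to an installed coupled leaf-canopy RTM, convolved/sampled to
    the ten band centers.  Requires the `prosail` library."""
    try:
        import prosail  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the 'prosail_pro' backend requires the optional 'prosail' "
            "library; install it or use backend='surrogate'"
        ) from exc
    spectrum = prosail.run_prosail(  # pragma: no cover
        n=params.Nstruct,
        cab=params.Cab,
        car=params.Cxc,
        cbrown=params.Cbrown,
        cw=params.EWT,
        cm=params.Cm,
        lai=params.LAI,
        lidfa=params.ALIA,
        hspot=params.Hot,
        tts=params.SZA,
        tto=params.OZA,
        psi=params.rAA,
        rsoil=params.soil,
        psoil=1.0,
        typelidf=2,
    )
    wavelengths = np.arange(400, 2501)  # pragma: no cover
    idx = np.searchsorted(wavelengths, BAND_CENTERS_NM)  # pragma: no cover
    return np.clip(spectrum[idx], 0.0, 1.0)  # pragma: no cover


def forward_reflectance(
    params: RTMParams, backend: str = "surrogate"
) -> SpectralSample:
    """Simulate 10-band canopy reflectance for one parameter vector."""
    if backend not in ("surrogate", "prosail_pro"):
        raise ValueError(f"unknown backend {backend!r}")
    _check_physical(params)
    if backend == "surrogate":
        refl = _surrogate_reflectance(
            params.Cab, params.EWT, params.Cm, params.CBC,
            params.LAI, params.ALIA, params.soil,
        )[0]
    else:
        refl = _prosail_reflectance(params)
    return SpectralSample(reflectance=refl)


def simulate_fvc(lai, alia):
    """Fractional vegetation cover from a Beer-Lambert gap fraction:
    ``FVC = 1 - exp(-cos(ALIA) * LAI)``."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    fvc = 1.0 - np.exp(-np.cos(np.radians(np.asarray(alia, float))) * lai)
    return float(fvc) if fvc.ndim == 0 else fvc


def derive_labels(params: RTMParams, fvc: float) -> tuple[float, float, float]:
    """Canopy-level labels (LAI, CCC_s, VWC_s) from one parameter vector.

    CCC_s = Cab*LAI/100 [g m-2]; VWC_s = EWT*LAI*FVC*1e4 [g m-2].
    """
    if not 0.0 <= fvc <= 1.0:
        raise ValueError(f"fvc must be in [0, 1], got {fvc}")
    ccc = params.Cab * params.LAI / 100.0
    vwc = params.EWT * params.LAI * fvc * 1e4
    return params.LAI, ccc, vwc


def build_training_db(
    n: int = 1000,
    seed: int = 0,
    backend: str = "surrogate",
    ranges: dict[str, tuple[float, float]] | None = None,
) -> TrainingSet:
    """LHS-sampled vegetated training database, deterministic under seed."""
    samples = sample_lhs(n, ranges=ranges, seed=seed)
    if backend == "surrogate":
        arr = {k: np.array([getattr(p, k) for p in samples]) for k in
               ("Cab", "EWT", "Cm", "CBC", "LAI", "ALIA", "soil")}
        spectra = _surrogate_reflectance(
            arr["Cab"], arr["EWT"], arr["Cm"], arr["CBC"],
            arr["LAI"], arr["ALIA"], arr["soil"],
        )
    else:
        spectra = np.vstack(
            [forward_reflectance(p, backend).reflectance for p in samples]
        )
    lai = np.array([p.LAI for p in samples])
    alia = np.array([p.ALIA for p in samples])
    cab = np.array([p.Cab for p in samples])
    ewt = np.array([p.EWT for p in samples])
    fvc = simulate_fvc(lai, alia)
    ccc = cab * lai / 100.0
    vwc = ewt * lai * fvc * 1e4
    return TrainingSet(
        spectra=spectra,
        lai=lai,
        ccc=ccc,
        vwc=vwc,
        fvc=fvc,
        provenance=np.array(["vegetated"] * n),
        meta={
            "seed": seed,
            "backend": backend,
            "n": n,
            "ranges": {k: list(v) for k, v in (ranges or TABLE1_RANGES).items()},
            "surrogate_version": SURROGATE_VERSION,
        },
    )


# Draw ranges for augmentation samples (senescent canopies keep structure but
# lose pigments and water; bare records are pure soil).
SENESCENT_RANGES = {"Cab": (1.0, 5.0), "EWT": (0.0002, 0.002), "LAI": (1.0, 5.0)}


def augment_nonvegetated(
    ts: TrainingSet,
    n_bare: int = 12,
    n_senescent: int = 27,
    seed: int = 0,
    backend: str = "surrogate",
) -> TrainingSet:
    """Append bare-soil and senescent-crop samples to a training set.

    Bare samples have LAI = 0 (all labels zero) and random soil brightness;
    senescent samples have low chlorophyll, near-zero water and retained
    leaf area, with labels from :func:`derive_labels`.
    """
    if n_bare < 0 or n_senescent < 0:
        raise ValueError("augmentation counts must be non-negative")
    if n_bare == 0 and n_senescent == 0:
        return ts
    rng = np.random.default_rng(seed)
    mid = _default_free()
    parts = [ts]
    if n_bare > 0:
        soil = rng.uniform(0.0, 1.0, n_bare)
        spectra = _surrogate_reflectance(
            np.full(n_bare, mid["Cab"]), np.full(n_bare, mid["EWT"]),
            np.full(n_bare, mid["Cm"]), np.full(n_bare, mid["CBC"]),
            np.zeros(n_bare), np.full(n_bare, mid["ALIA"]), soil,
        )
        parts.append(TrainingSet(
            spectra=spectra,
            lai=np.zeros(n_bare), ccc=np.zeros(n_bare), vwc=np.zeros(n_bare),
            fvc=np.zeros(n_bare),
            provenance=np.array(["bare"] * n_bare),
        ))
    if n_senescent > 0:
        cab = rng.uniform(*SENESCENT_RANGES["Cab"], n_senescent)
        ewt = rng.uniform(*SENESCENT_RANGES["EWT"], n_senescent)
        lai = rng.uniform(*SENESCENT_RANGES["LAI"], n_senescent)
        alia = rng.uniform(*TABLE1_RANGES["ALIA"], n_senescent)
        soil = rng.uniform(0.0, 1.0, n_senescent)
        cm = rng.uniform(*TABLE1_RANGES["Cm"], n_senescent)
        cbc = rng.uniform(*TABLE1_RANGES["CBC"], n_senescent)
        spectra = _surrogate_reflectance(cab, ewt, cm, cbc, lai, alia, soil)
        fvc = simulate_fvc(lai, alia)
        parts.append(TrainingSet(
            spectra=spectra,
            lai=lai,
            ccc=cab * lai / 100.0,
            vwc=ewt * lai * fvc * 1e4,
            fvc=fvc,
            provenance=np.array(["senescent"] * n_senescent),
        ))
    out = parts[0]
    for p in parts[1:]:
        out = out.concat(p)
    out.meta = dict(ts.meta, n_bare=n_bare, n_senescent=n_senescent,
                    augment_seed=seed)
    return out
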