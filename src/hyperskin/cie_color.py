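"""Colorimetric kernel: spectra, tristimulus integration, Lab, CIEDE2000.

Every spectrum in the package lives on the fixed visible grid 380–780 nm at
1 nm (401 samples).  Tristimulus integration follows the CIE recipe

    X = k * sum( S(l) * R(l) * xbar(l) * dl ),   dl = 1 nm,

with the brightness ratio ``k = 100 / sum(S * ybar * dl)`` normalising the
illuminant's luminance to Y = 100.  The integrals are evaluated as plain
1 nm Riemann sums; at this tabulation the quadrature rule is immaterial.

The CIEDE2000 colour difference is implemented from the standard formulation
(Sharma, Wu & Dalal 2005) with unit parametric factors, and is cross-checked
against scikit-image's implementation in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateIlluminantError,
    ValidationError,
)

#: The common wavelength grid (nm): 380, 381, ..., 780.
WAVELENGTHS_NM = np.arange(380.0, 781.0, 1.0)
N_BANDS = WAVELENGTHS_NM.size  # 401

SPECTRUM_KINDS = ("reflectance", "illuminant", "reconstructed")
PROVENANCES = ("camera", "spectrometer", "corrected")

# IEC 61966-2-1 sRGB (D65) linear-RGB -> XYZ matrix.  The Y row sums to 1,
# so (255,255,255) maps to Y = 100 exactly on the 0-100 scale.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0556, 0.1192, 0.9505],
    ]
)
_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ)


@dataclass(frozen=True)
class Spectrum:
    """Values on the fixed 380–780 nm / 1 nm grid.

    ``kind`` distinguishes reflectance (unitless, roughly [0, 1.2]),
    illuminant spectral power (nonnegative, arbitrary units) and
    reconstructed reflectance (may slightly over/undershoot [0, 1]).
    """

    values: np.ndarray
    kind: str = "reflectance"
    wavelengths_nm: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise ValidationError(f"unknown spectrum kind {self.kind!r}")
        if values.shape != (N_BANDS,):
            raise ValidationError(
                f"spectrum must have {N_BANDS} samples, got shape {values.shape}"
            )
        if wl.shape != (N_BANDS,) or not np.allclose(wl, WAVELENGTHS_NM):
            raise ValidationError("wavelength grid must be 380..780 nm step 1 nm")
        if not np.all(np.isfinite(values)):
            raise ValidationError("spectrum contains non-finite values")
        if self.kind == "illuminant" and np.any(values < 0):
            raise ValidationError("illuminant power must be nonnegative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "wavelengths_nm", wl)

    @classmethod
    def flat(cls, value: float, kind: str = "reflectance") -> "Spectrum":
        return cls(np.full(N_BANDS, float(value)), kind=kind)

    def clipped(self, lo: float = 0.0, hi: float = 1.2) -> "Spectrum":
        """Display-clipped copy; error metrics use the unclipped values."""
        return Spectrum(np.clip(self.values, lo, hi), kind=self.kind)


@dataclass(frozen=True)
class CMFSet:
    """CIE 1931 2-degree standard-observer colour matching functions."""

    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_BANDS,):
                raise ValidationError(f"{name} must have {N_BANDS} samples")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} must be finite and nonnegative")
            object.__setattr__(self, name, arr)

    def as_matrix(self) -> np.ndarray:
        """3 x 401 stack (xbar, ybar, zbar rows)."""
        return np.vstack([self.xbar, self.ybar, self.zbar])


@dataclass(frozen=True)
class Whitepoint:
    """Illuminant tristimulus with Yn pinned to 100, plus the brightness ratio k."""

    k: float
    Xn: float
    Yn: float
    Zn: float

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValidationError("brightness ratio k must be positive")
        if self.Yn != 100.0:
            raise ValidationError("whitepoint Yn must equal 100")


@dataclass(frozen=True)
class TristimulusXYZ:
    """CIE XYZ on the Y in [0, 100] scale, tagged with its provenance."""

    X: float
    Y: float
    Z: float
    provenance: str = "spectrometer"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if not all(math.isfinite(v) for v in (self.X, self.Y, self.Z)):
            raise ValidationError("XYZ components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class LabColor:
    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])


# ---------------------------------------------------------------------------
# CMF loading

_CMF_RESOURCE = "cie1931_cmf_2deg.csv"


def load_cmf() -> CMFSet:
    """Load the bundled CIE 1931 2-degree observer table (380–780 nm, 1 nm).

    The table is tabulated from the multi-lobe Gaussian analytic fit of
    Wyman, Sloan & Shirley (2013), accurate to about 1% of peak, which is
    ample for a calibration pipeline that uses the same functions on both
    the camera and the spectrometer side.
    """
    try:
        ref = resources.files("hyperskin.data").joinpath(_CMF_RESOURCE)
        table = pd.read_csv(ref.open("r"))
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover
        raise ConfigurationError(f"bundled CMF table missing: {exc}") from exc
    expected = {"wavelength_nm", "xbar", "ybar", "zbar"}
    if set(table.columns) != expected or len(table) != N_BANDS:
        raise ConfigurationError("bundled CMF table is corrupt")
    return CMFSet(
        table["xbar"].to_numpy(),
        table["ybar"].to_numpy(),
        table["zbar"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Tristimulus integration


def spectrum_to_xyz(
    R: Spectrum, S: Spectrum, cmf: CMFSet | None = None
) -> tuple[TristimulusXYZ, Whitepoint]:
    """Integrate reflectance R under illuminant S to tristimulus XYZ.

    Returns the spectrometer-provenance XYZ and the session whitepoint
    (tristimulus of the illuminant itself, i.e. R identically 1, so Yn = 100
    by construction of k).
    """
    if cmf is None:
        cmf = load_cmf()
    s = S.values
    denom = float(np.sum(s * cmf.ybar))
    if denom <= 0.0:
        raise DegenerateIlluminantError("illuminant integrates to zero luminance")
    k = 100.0 / denom
    sr = s * R.values
    xyz = TristimulusXYZ(
        k * float(np.sum(sr * cmf.xbar)),
        k * float(np.sum(sr * cmf.ybar)),
        k * float(np.sum(sr * cmf.zbar)),
        provenance="spectrometer",
    )
    wp = Whitepoint(
        k=k,
        Xn=k * float(np.sum(s * cmf.xbar)),
        Yn=100.0,
        Zn=k * float(np.sum(s * cmf.zbar)),
    )
    return xyz, wp


def spectra_to_xyz_array(
    reflectances: np.ndarray, S: Spectrum, cmf: CMFSet | None = None
) -> np.ndarray:
    """Vectorised variant: (n, 401) reflectances -> (n, 3) XYZ rows."""
    if cmf is None:
        cmf = load_cmf()
    refl = np.atleast_2d(np.asarray(reflectances, dtype=float))
    if refl.shape[1] != N_BANDS:
        raise ValidationError("reflectance rows must have 401 samples")
    denom = float(np.sum(S.values * cmf.ybar))
    if denom <= 0.0:
        raise DegenerateIlluminantError("illuminant integrates to zero luminance")
    k = 100.0 / denom
    weighted = cmf.as_matrix() * S.values  # 3 x 401
    return k * refl @ weighted.T


# ---------------------------------------------------------------------------
# sRGB


def _srgb_decode(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_encode(c: np.ndarray) -> np.ndarray:
    c = np.clip(np.asarray(c, dtype=float), 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1.0 / 2.4) - 0.055)


def srgb_to_xyz(rgb: Sequence[float]) -> TristimulusXYZ:
    """Decode an 8-bit sRGB triple to camera-provenance XYZ (Y in [0, 100]).

    Applies the IEC 61966-2-1 inverse companding then the sRGB/D65 matrix;
    white (255, 255, 255) maps to Y = 100.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,):
        raise ValidationError("rgb must be a triple")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValidationError("rgb channels must lie in [0, 255]")
    xyz = 100.0 * _SRGB_TO_XYZ @ _srgb_decode(arr / 255.0)
    return TristimulusXYZ(*map(float, xyz), provenance="camera")


def srgb_to_xyz_array(rgb: np.ndarray) -> np.ndarray:
    """Vectorised sRGB decode: (n, 3) 8-bit values -> (n, 3) camera XYZ."""
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError("rgb array must be n x 3")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValidationError("rgb channels must lie in [0, 255]")
    return 100.0 * _srgb_decode(arr / 255.0) @ _SRGB_TO_XYZ.T


def xyz_to_srgb_array(xyz: np.ndarray, quantize: bool = True) -> np.ndarray:
    """Encode (n, 3) XYZ rows (Y scale 0-100) to sRGB; out-of-gamut clipped."""
    linear = np.asarray(xyz, dtype=float) / 100.0 @ _XYZ_TO_SRGB.T
    srgb = _srgb_encode(linear) * 255.0
    if quantize:
        return np.clip(np.rint(srgb), 0, 255).astype(np.uint8)
    return srgb


# ---------------------------------------------------------------------------
# Lab and colour difference


def xyz_to_lab(xyz: TristimulusXYZ, wp: Whitepoint) -> LabColor:
    """CIE L*a*b* with the piecewise cube-root companding, relative to wp."""
    if wp.Xn <= 0 or wp.Zn <= 0:
        raise ValidationError("whitepoint components must be positive")

    def f(t: float) -> float:
        d = 6.0 / 29.0
        if t > d**3:
            return t ** (1.0 / 3.0)
        return t / (3.0 * d * d) + 4.0 / 29.0

    fx = f(xyz.X / wp.Xn)
    fy = f(xyz.Y / wp.Yn)
    fz = f(xyz.Z / wp.Zn)
    return LabColor(116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))


def ciede2000(lab1: LabColor | Sequence[float], lab2: LabColor | Sequence[float]) -> float:
    """CIEDE2000 colour difference with parametric factors kL = kC = kH = 1."""
    L1, a1, b1 = _lab_triple(lab1)
    L2, a2, b2 = _lab_triple(lab2)

    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - math.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1.0 + G) * a1, (1.0 + G) * a2
    C1p = math.hypot(a1p, b1)
    C2p = math.hypot(a2p, b2)

    h1p = math.degrees(math.atan2(b1, a1p)) % 360.0 if C1p else 0.0
    h2p = math.degrees(math.atan2(b2, a2p)) % 360.0 if C2p else 0.0

    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        dhp = h2p - h1p
        if dhp > 180.0:
            dhp -= 360.0
        elif dhp < -180.0:
            dhp += 360.0
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0.0:
        hbp = h1p + h2p
    elif abs(h1p - h2p) <= 180.0:
        hbp = 0.5 * (h1p + h2p)
    elif h1p + h2p < 360.0:
        hbp = 0.5 * (h1p + h2p + 360.0)
    else:
        hbp = 0.5 * (h1p + h2p - 360.0)

    T = (
        1.0
        - 0.17 * math.cos(math.radians(hbp - 30.0))
        + 0.24 * math.cos(math.radians(2.0 * hbp))
        + 0.32 * math.cos(math.radians(3.0 * hbp + 6.0))
        - 0.20 * math.cos(math.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * math.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * math.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / math.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -math.sin(math.radians(2.0 * dtheta)) * RC

    tL = dLp / SL
    tC = dCp / SC
    tH = dHp / SH
    return math.sqrt(tL * tL + tC * tC + tH * tH + RT * tC * tH)


def _lab_triple(lab: LabColor | Sequence[float]) -> tuple[float, float, float]:
    if isinstance(lab, LabColor):
        return lab.L, lab.a, lab.b
    L, a, b = (float(v) for v in lab)
    return L, a, b


# ---------------------------------------------------------------------------
# Spectral error


def rmse_spectra(a: Spectrum, b: Spectrum) -> float:
    """Root-mean-square difference over the 401 shared samples."""
    if not np.allclose(a.wavelengths_nm, b.wavelengths_nm):
        raise ValidationError("spectra must share the wavelength grid")
    diff = a.values - b.values
    return float(np.sqrt(np.mean(diff * diff)))


# ---------------------------------------------------------------------------
# CSV I/O for spectra


def read_spectrum_csv(path) -> Spectrum:
    """Read a single spectrum from a two-column CSV (wavelength_nm, value)."""
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValidationError("spectrum CSV needs wavelength and value columns")
    return Spectrum(table.iloc[:, 1].to_numpy(), wavelengths_nm=table.iloc[:, 0].to_numpy())


def read_spectra_wide_csv(path) -> list[Spectrum]:
    """Read a wide CSV: first column wavelength_nm, one column per sample."""
    table = pd.read_csv(path)
    wl = table.iloc[:, 0].to_numpy()
    return [Spectrum(table[c].to_numpy(), wavelengths_nm=wl) for c in table.columns[1:]]


def write_spectra_wide_csv(path, spectra: Iterable[Spectrum], names=None) -> None:
    spectra = list(spectra)
    if names is None:
        names = [f"sample_{i + 1}" for i in range(len(spectra))]
    data = {"wavelength_nm": WAVELENGTHS_NM.astype(int)}
    for name, sp in zip(names, spectra):
        data[name] = sp.values
    pd.DataFrame(data).to_csv(path, index=False)
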