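"""Synthetic fixtures: reflectance spectra, camera forward model, checker
scenes and 4-class lesion image datasets.

The generators emulate the structure the calibration and classification
pipeline depends on, not any particular physical instrument:

* reflectance spectra are positive combinations of a fixed dictionary of
  broad Gaussian bands plus a flat baseline, so a 24-draw set has effective
  linear dimension at most 12 (mirroring the low intrinsic dimensionality
  of natural-object reflectances);
* the camera forward model distorts true XYZ with a monotone polynomial
  tone curve, a dark-current offset and zero-mean chrominance noise on X
  and Z — exactly the error taxonomy the 20-term correction matrix is
  designed to invert;
* lesion images carry class-specific spectral signatures (haemoglobin-like
  absorption around 540–580 nm and broad long-wavelength slope changes)
  whose strength is a single separation parameter, so classes can be made
  RGB-subtle but spectrally separable;
* the neutral patches 19–24 of the synthetic checker form a strictly
  descending gray ramp, as required by the nonlinearity diagnostic.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cie_color import (
    N_BANDS,
    WAVELENGTHS_NM,
    CMFSet,
    Spectrum,
    load_cmf,
    spectra_to_xyz_array,
    xyz_to_srgb_array,
)
from .errors import ValidationError

#: Canonical class order used throughout the classification code.
CLASSES = ("MF", "PsO", "AD", "normal")

#: Neutral-ramp reflectance levels for checker patches 19-24 (descending).
GRAY_RAMP_LEVELS = (0.88, 0.57, 0.35, 0.19, 0.085, 0.031)

# Fixed dictionary of broad Gaussian band centres (nm); together with the
# flat baseline the spectra span at most an 11-dimensional subspace.
_BAND_CENTERS = np.array([420.0, 455.0, 490.0, 525.0, 560.0, 600.0, 640.0, 680.0, 730.0])
_BAND_SIGMA = 55.0

# Per-band weight scales with a decaying profile: real surface reflectances
# concentrate their variance in a handful of dominant smooth modes, and the
# XYZ-to-spectrum regression relies on that concentration.
_BAND_SCALES = np.array([0.12, 0.30, 0.10, 0.45, 0.05, 0.25, 0.08, 0.04, 0.02])


def _gauss(center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((WAVELENGTHS_NM - center) / sigma) ** 2)


_BAND_DICT = np.vstack([_gauss(c, _BAND_SIGMA) for c in _BAND_CENTERS])  # 9 x 401


# ---------------------------------------------------------------------------
# Reference fixture


def load_checker_lab_reference() -> pd.DataFrame:
    """Bundled cross-calibration reference for a 24-patch checker session.

    Columns: patch_id, measured L*/a*/b*, simulated L*/a*/b*, and the
    CIEDE2000 value reported for each pair (reported mean 0.28).
    """
    ref = resources.files("hyperskin.data").joinpath("checker_lab_reference.csv")
    return pd.read_csv(ref.open("r"))


# ---------------------------------------------------------------------------
# Spectra and illuminant


def generate_reflectance_spectra(
    n: int,
    seed: int = 0,
    n_bands: tuple[int, int] = (3, 6),
    baseline_range: tuple[float, float] = (0.08, 0.30),
    band_scales: np.ndarray | None = None,
) -> list[Spectrum]:
    """Draw n smooth natural-object-like reflectance spectra.

    Each spectrum is a flat baseline plus 3-6 bands from the fixed broad
    Gaussian dictionary with positive weights, rescaled into [0.02, 0.95].
    Band weights follow the decaying per-band scales, so a 24-draw set has
    its variance concentrated in a few dominant modes (effective linear
    dimension well under 12).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    scales = _BAND_SCALES if band_scales is None else np.asarray(band_scales, float)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = rng.integers(n_bands[0], n_bands[1] + 1)
        idx = rng.choice(len(_BAND_CENTERS), size=k, replace=False)
        weights = rng.uniform(0.2, 1.0, size=k) * scales[idx]
        baseline = rng.uniform(*baseline_range)
        values = baseline + weights @ _BAND_DICT[idx]
        peak = values.max()
        if peak > 0.95:  # uniform rescale keeps the draw inside the band span
            values *= 0.95 / peak
        out.append(Spectrum(np.clip(values, 0.02, 0.95)))
    return out


def default_illuminant(temperature_k: float = 5500.0) -> Spectrum:
    """Smooth broadband illuminant: Planckian radiator, peak-normalised.

    The imaging sessions being emulated used an unspecified stable studio
    source; a 5500 K blackbody is a realistic stand-in.
    """
    h, c, kb = 6.62607e-34, 2.99792e8, 1.380649e-23
    lam = WAVELENGTHS_NM * 1e-9
    power = (1.0 / lam**5) / (np.exp(h * c / (lam * kb * temperature_k)) - 1.0)
    return Spectrum(power / power.max(), kind="illuminant")


# ---------------------------------------------------------------------------
# Camera forward model


@dataclass(frozen=True)
class CameraModel:
    """Parametric forward model of the camera's XYZ-domain error sources.

    ``gamma_poly`` holds ascending-power coefficients of the tone curve
    f(v) = c1*v + c2*v^2 + c3*v^3 applied to each XYZ channel on the
    v = value/100 scale; it must be monotone on [0, 1].  ``dark_offset``
    (Y-units) is added to every channel; zero-mean Gaussian chrominance
    noise of sd ``chroma_noise_sd`` is added to X and Z only.
    """

    gamma_poly: tuple[float, ...] = (0.85, 0.10, 0.05)
    dark_offset: float = 1.0
    chroma_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chroma_noise_sd < 0:
            raise ValidationError("noise sd must be nonnegative")
        v = np.linspace(0.0, 1.0, 256)
        tone = self.tone_curve(v)
        if np.any(np.diff(tone) <= 0):
            raise ValidationError("tone curve must be strictly monotone on [0, 1]")

    @classmethod
    def ideal(cls) -> "CameraModel":
        return cls(gamma_poly=(1.0,), dark_offset=0.0, chroma_noise_sd=0.0)

    def tone_curve(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        for power, coef in enumerate(self.gamma_poly, start=1):
            out += coef * v**power
        return out

    def distort_xyz(self, xyz_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Apply tone curve, dark offset and chrominance noise to (n, 3) XYZ."""
        arr = np.atleast_2d(np.asarray(xyz_rows, dtype=float))
        out = 100.0 * self.tone_curve(arr / 100.0)
        out = out + self.dark_offset
        if self.chroma_noise_sd > 0:
            noise = rng.normal(0.0, self.chroma_noise_sd, size=(arr.shape[0], 2))
            out[:, 0] += noise[:, 0]
            out[:, 2] += noise[:, 1]
        return out


def simulate_camera_response(
    R: Spectrum,
    S: Spectrum,
    cam: CameraModel,
    cmf: CMFSet | None = None,
    quantize: bool = True,
):
    """One patch through the camera: (8-bit sRGB triple, camera XYZ triple)."""
    rgb, xyz = simulate_camera_responses([R], S, cam, cmf=cmf, quantize=quantize)
    return rgb[0], xyz[0]


def simulate_camera_responses(
    spectra,
    S: Spectrum,
    cam: CameraModel,
    cmf: CMFSet | None = None,
    quantize: bool = True,
    rng: np.random.Generator | None = None,
):
    """Vectorised camera simulation for a batch of reflectance spectra.

    Returns (rgb, camera_xyz): the encoded sRGB values (8-bit if
    ``quantize``) and the distorted XYZ before encoding.
    """
    if cmf is None:
        cmf = load_cmf()
    if rng is None:
        rng = np.random.default_rng(cam.seed)
    refl = np.vstack([sp.values for sp in spectra])
    true_xyz = spectra_to_xyz_array(refl, S, cmf)
    cam_xyz = cam.distort_xyz(true_xyz, rng)
    rgb = xyz_to_srgb_array(cam_xyz, quantize=quantize)
    return rgb, cam_xyz


# ---------------------------------------------------------------------------
# Checker scene


@dataclass
class CheckerScene:
    """A synthetic 24-patch checker session: 18 chromatic + 6 gray-ramp patches."""

    spectra: list
    illuminant: Spectrum
    camera_rgb: np.ndarray  # 24 x 3 uint8
    camera_xyz: np.ndarray  # 24 x 3, distorted
    true_xyz: np.ndarray  # 24 x 3, spectrometer ground truth


def generate_checker_scene(
    seed: int = 0,
    cam: CameraModel | None = None,
    cmf: CMFSet | None = None,
    quantize: bool = True,
) -> CheckerScene:
    if cam is None:
        cam = CameraModel()
    if cmf is None:
        cmf = load_cmf()
    spectra = generate_reflectance_spectra(18, seed=seed)
    spectra += [Spectrum.flat(level) for level in GRAY_RAMP_LEVELS]
    illuminant = default_illuminant()
    refl = np.vstack([sp.values for sp in spectra])
    true_xyz = spectra_to_xyz_array(refl, illuminant, cmf)
    rng = np.random.default_rng(seed + cam.seed)
    cam_xyz = cam.distort_xyz(true_xyz, rng)
    rgb = xyz_to_srgb_array(cam_xyz, quantize=quantize)
    return CheckerScene(
        spectra=spectra,
        illuminant=illuminant,
        camera_rgb=rgb,
        camera_xyz=cam_xyz,
        true_xyz=true_xyz,
    )


# ---------------------------------------------------------------------------
# Lesion dataset


@dataclass(frozen=True)
class SceneSpec:
    """Configuration of a synthetic lesion-image dataset."""

    n_patients: int = 20
    images_per_patient: int = 10
    class_proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    image_size: tuple[int, int] = (64, 64)
    lesion_axes_frac: tuple[float, float] = (0.15, 0.35)
    separation: float = 1.0
    patient_sd: float = 0.06
    within_class_jitter: float = 0.10
    rgb_noise_sd: float = 1.5
    seed: int = 0
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.images_per_patient < 1:
            raise ValidationError("counts must be >= 1")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        if len(self.class_proportions) != len(CLASSES):
            raise ValidationError("one proportion per class required")


@dataclass
class LesionImage:
    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W bool ground truth (empty for normal skin)
    label: str
    patient_id: str
    image_id: str


@dataclass
class LesionDataset:
    images: list
    illuminant: Spectrum
    camera: CameraModel

    def __iter__(self):
        return iter(self.images)

    def __len__(self):
        return len(self.images)


def _skin_spectrum(brightness: float, hb_depth: float = 0.11) -> np.ndarray:
    """Skin-like reflectance: melanin slope with haemoglobin dips."""
    slope = 0.18 + 0.42 / (1.0 + np.exp(-(WAVELENGTHS_NM - 580.0) / 65.0))
    dips = hb_depth * _gauss(542.0, 12.0) + 0.9 * hb_depth * _gauss(577.0, 10.0)
    return np.clip(brightness * slope * (1.0 - dips), 0.02, 0.95)


# Class-specific spectral signatures: fractional absorption profiles applied
# to the base skin spectrum.  MF: strong erythema (deep 540-580 absorption
# plus a 590-610 shoulder); PsO: moderate absorption with a *brightening*
# long-wavelength term (silvery scale); AD: mild erythema shifted bluewards.
_CLASS_PROFILES = {
    "MF": 0.30 * _gauss(550.0, 25.0) + 0.16 * _gauss(595.0, 18.0),
    "PsO": 0.22 * _gauss(540.0, 30.0) - 0.14 * _gauss(660.0, 55.0),
    "AD": 0.16 * _gauss(560.0, 35.0) + 0.10 * _gauss(480.0, 30.0),
    "normal": np.zeros(N_BANDS),
}


def class_lesion_spectrum(
    label: str, skin: np.ndarray, separation: float, jitter: float = 0.0
) -> np.ndarray:
    """Lesion reflectance for a class: skin modulated by its signature."""
    profile = _CLASS_PROFILES[label]
    return np.clip(skin * (1.0 - separation * (1.0 + jitter) * profile), 0.02, 0.95)


def _ellipse_mask(
    shape: tuple[int, int], rng: np.random.Generator, axes_frac: tuple[float, float]
) -> np.ndarray:
    h, w = shape
    cy = rng.uniform(0.35, 0.65) * h
    cx = rng.uniform(0.35, 0.65) * w
    ay = rng.uniform(*axes_frac) * h
    ax = rng.uniform(*axes_frac) * w
    theta = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def _patient_class_assignment(spec: SceneSpec) -> list[str]:
    """Assign each patient a single disease class, matching proportions by
    largest-remainder rounding."""
    raw = np.array(spec.class_proportions) * spec.n_patients
    counts = np.floor(raw).astype(int)
    remainder = spec.n_patients - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    labels: list[str] = []
    for cls, cnt in zip(CLASSES, counts):
        labels.extend([cls] * cnt)
    return labels


def generate_lesion_dataset(spec: SceneSpec, cmf: CMFSet | None = None) -> LesionDataset:
    """Render a deterministic 4-class lesion image dataset with truth masks.

    Each patient carries one disease class and an individual skin
    brightness; each image renders a skin field (smooth illumination
    gradient plus pixel noise) and, for disease classes, an elliptical
    lesion whose spectrum carries the class signature scaled by
    ``spec.separation``.  Pixels are passed through the configured camera
    model, so the rendered RGB is consistent with a checker scene shot by
    the same camera under the same illuminant.
    """
    if cmf is None:
        cmf = load_cmf()
    rng = np.random.default_rng(spec.seed)
    illuminant = default_illuminant()
    weighted_cmf = cmf.as_matrix() * illuminant.values  # 3 x 401
    k = 100.0 / float(np.sum(illuminant.values * cmf.ybar))

    patient_classes = _patient_class_assignment(spec)
    h, w = spec.image_size
    images: list[LesionImage] = []
    for p, label in enumerate(patient_classes):
        patient_id = f"P{p:03d}"
        brightness = rng.normal(1.0, spec.patient_sd)
        skin = _skin_spectrum(np.clip(brightness, 0.7, 1.3))
        for j in range(spec.images_per_patient):
            image_id = f"{patient_id}_I{j:03d}"
            jitter = rng.normal(0.0, spec.within_class_jitter)
            lesion = class_lesion_spectrum(label, skin, spec.separation, jitter)
            if label == "normal":
                mask = np.zeros((h, w), dtype=bool)
            else:
                mask = _ellipse_mask((h, w), rng, spec.lesion_axes_frac)

            base = np.vstack([skin, lesion])  # 2 x 401
            xyz_pair = k * base @ weighted_cmf.T  # 2 x 3
            cam_xyz_pair = spec.camera.distort_xyz(xyz_pair, rng)

            # smooth multiplicative illumination gradient across the frame
            gy = np.linspace(-1.0, 1.0, h)[:, None]
            gx = np.linspace(-1.0, 1.0, w)[None, :]
            direction = rng.uniform(0.0, 2.0 * np.pi)
            grad = 1.0 + 0.05 * (np.cos(direction) * gx + np.sin(direction) * gy)

            xyz_field = np.where(
                mask[..., None], cam_xyz_pair[1], cam_xyz_pair[0]
            ) * grad[..., None]
            rgb = xyz_to_srgb_array(xyz_field.reshape(-1, 3), quantize=False)
            rgb = rgb + rng.normal(0.0, spec.rgb_noise_sd, size=rgb.shape)
            rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8).reshape(h, w, 3)

            images.append(
                LesionImage(
                    image=rgb,
                    mask=mask,
                    label=label,
                    patient_id=patient_id,
                    image_id=image_id,
                )
            )
    return LesionDataset(images=images, illuminant=illuminant, camera=spec.camera)
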