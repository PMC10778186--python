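"""Image and mask handling: stand-in lesion segmentation, overlap metrics,
and per-pixel hyperspectral cube construction.

The deep segmentation model whose role this module fills was trained on
private clinical data; its job in the pipeline is deliberately coarse —
separate lesion from healthy skin so the spectral classifier sees clean
regions.  The stand-in here thresholds a redness statistic (the CIELAB a*
opponent channel) at median + c*MAD and tidies the result with binary
morphology.  External masks (e.g. exported from any segmentation model)
are accepted through the same :class:`LesionMask` type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from skimage.morphology import closing, disk, opening

from .calibration import CalibrationModel, apply_correction_array
from .cie_color import N_BANDS, srgb_to_xyz_array
from .errors import ModelIncompleteError, ValidationError
from .spectral_model import SpectralBasis, reconstruct_spectra_array


@dataclass(frozen=True)
class LesionMask:
    """Binary H x W lesion mask paired with an image."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValidationError("mask must be 2-d")
        if grid.dtype != bool:
            uniq = np.unique(grid)
            if not np.all(np.isin(uniq, (0, 1, 255))):
                raise ValidationError("mask values must be binary")
            grid = grid > 0
        object.__setattr__(self, "grid", grid)

    @property
    def lesion_fraction(self) -> float:
        return float(self.grid.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class SegmentationScore:
    dice: float
    iou: float
    cross_entropy: float | None = None


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding parameters of the stand-in segmenter.

    The statistic is the a* channel of the image in CIELAB (red-green
    opponent axis; erythematous lesions sit high).  Threshold is
    median + ``mad_factor`` * MAD unless ``absolute_threshold`` is given.
    ``softness`` scales the logistic squash used for the probability map.
    """

    mad_factor: float = 3.0
    absolute_threshold: float | None = None
    opening_radius: int = 2
    closing_radius: int = 2
    softness: float = 2.0


def _redness(image: np.ndarray) -> np.ndarray:
    lab = rgb2lab(image)
    return lab[..., 1]


def segment_lesion(
    image: np.ndarray, params: SegmentationParams | None = None
) -> LesionMask:
    """Threshold-and-morphology stand-in segmenter; deterministic."""
    mask, _ = segment_lesion_soft(image, params)
    return mask


def segment_lesion_soft(
    image: np.ndarray, params: SegmentationParams | None = None
) -> tuple[LesionMask, np.ndarray]:
    """Segment and also return the squashed (0, 1) probability map."""
    if params is None:
        params = SegmentationParams()
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ValidationError("image must be H x W x 3 uint8 RGB")

    stat = _redness(arr)
    if params.absolute_threshold is not None:
        thr = params.absolute_threshold
        scale = max(params.softness, 1e-6)
    else:
        med = float(np.median(stat))
        mad = float(np.median(np.abs(stat - med)))
        thr = med + params.mad_factor * mad
        scale = max(params.softness * max(mad, 1e-6), 1e-6)

    raw = stat > thr
    if params.opening_radius > 0:
        raw = opening(raw, disk(params.opening_radius))
    if params.closing_radius > 0:
        raw = closing(raw, disk(params.closing_radius))
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-(stat - thr) / scale))
    prob = np.clip(prob, 1e-7, 1.0 - 1e-7)
    return LesionMask(raw), prob


def segmentation_metrics(
    pred: LesionMask, truth: LesionMask, prob: np.ndarray | None = None
) -> SegmentationScore:
    """Dice, IoU and (given probabilities) mean binary cross-entropy.

    Two empty masks count as perfect agreement (dice = iou = 1).
    """
    if pred.shape != truth.shape:
        raise ValidationError("mask dimensions differ")
    a, b = pred.grid, truth.grid
    inter = float(np.sum(a & b))
    a_sum, b_sum = float(a.sum()), float(b.sum())
    union = a_sum + b_sum - inter
    if a_sum + b_sum == 0.0:
        dice, iou = 1.0, 1.0
    else:
        dice = 2.0 * inter / (a_sum + b_sum)
        iou = inter / union if union else 1.0

    ce = None
    if prob is not None:
        p = np.clip(np.asarray(prob, dtype=float), 1e-7, 1.0 - 1e-7)
        if p.shape != truth.shape:
            raise ValidationError("probability map dimensions differ")
        t = truth.grid.astype(float)
        ce = float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))
    return SegmentationScore(dice=dice, iou=iou, cross_entropy=ce)


def image_to_cube(
    image: np.ndarray,
    calib: CalibrationModel,
    basis: SpectralBasis,
    mask: LesionMask | None = None,
) -> np.ndarray:
    """Per-pixel sRGB -> corrected XYZ -> spectrum; H x W x 401 float32.

    Pixels outside the mask (if given) are NaN sentinels — zero is a valid
    reflectance and must stay distinguishable from "excluded".  Identical
    input pixels always yield identical spectra (the map is purely
    per-pixel), which is exploited by computing each distinct RGB once.
    """
    if basis.M is None:
        raise ModelIncompleteError("basis has no transformation matrix M")
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ValidationError("image must be H x W x 3 uint8 RGB")
    h, w = arr.shape[:2]
    if mask is not None and mask.shape != (h, w):
        raise ValidationError("mask dimensions must match the image")

    flat = arr.reshape(-1, 3)
    colors, inverse = np.unique(flat, axis=0, return_inverse=True)
    cam_xyz = srgb_to_xyz_array(colors.astype(float))
    corrected = apply_correction_array(calib, cam_xyz)
    spectra = reconstruct_spectra_array(basis, corrected).astype(np.float32)

    cube = spectra[inverse].reshape(h, w, N_BANDS)
    if mask is not None:
        cube[~mask.grid] = np.nan
    return cube
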