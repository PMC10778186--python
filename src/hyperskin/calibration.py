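"""Camera error correction against spectrometer ground truth.

A consumer camera's XYZ response differs from the spectrometer's through
three error sources: a nonlinear tone response (well described by a cubic),
a dark-current offset, and chrominance noise that couples the X, Y, Z
channels.  All three are absorbed by a single least-squares correction:
each camera XYZ triple is expanded into a 20-term polynomial variable
vector

    V = [X^3 Y^3 Z^3 X^2Y X^2Z Y^2Z XY^2 XZ^2 YZ^2 XYZ
         X^2 Y^2 Z^2 XY XZ YZ X Y Z alpha]^T

and a 3 x 20 correction matrix C is fitted over the checker patches via the
Moore-Penrose pseudoinverse:

    C = [XYZ_spectrometer] @ pinv(V),      XYZ_corrected = C @ V.

The dark constant alpha is fixed at 1, which turns the last column of C
into a learned intercept that absorbs the dark level.

The grayscale-ramp nonlinearity analysis (polynomial fits of spectrometer Y
on camera Y for the six neutral patches) is diagnostic: it documents why
the cubic terms belong in V, but the correction itself flows only through C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cie_color import TristimulusXYZ
from .errors import InsufficientDataError, ProvenanceError, ValidationError

#: Names of the 20 polynomial terms, in their fixed order.
VARIABLE_TERMS = (
    "X3", "Y3", "Z3", "X2Y", "X2Z", "Y2Z", "XY2", "XZ2", "YZ2", "XYZ",
    "X2", "Y2", "Z2", "XY", "XZ", "YZ", "X", "Y", "Z", "alpha",
)

#: 1-based positions of the neutral gray-ramp patches on a standard checker.
DEFAULT_GRAY_PATCHES = (19, 20, 21, 22, 23, 24)

#: Relative singular-value cutoff for the pseudoinverse (numerical rank guard).
PINV_RTOL = 1e-10


def expand_variable_vector(
    xyz: TristimulusXYZ | Sequence[float], alpha: float = 1.0
) -> np.ndarray:
    """Expand one XYZ triple into the ordered 20-term variable vector."""
    x, y, z = _as_xyz_row(xyz)
    return np.array(
        [
            x**3, y**3, z**3,
            x * x * y, x * x * z, y * y * z,
            x * y * y, x * z * z, y * z * z,
            x * y * z,
            x * x, y * y, z * z,
            x * y, x * z, y * z,
            x, y, z,
            alpha,
        ]
    )


def expand_variable_matrix(xyz_rows: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Vectorised expansion: (n, 3) XYZ rows -> 20 x n variable matrix V."""
    arr = np.atleast_2d(np.asarray(xyz_rows, dtype=float))
    if arr.shape[1] != 3:
        raise ValidationError("xyz rows must be n x 3")
    x, y, z = arr[:, 0], arr[:, 1], arr[:, 2]
    cols = [
        x**3, y**3, z**3,
        x * x * y, x * x * z, y * y * z,
        x * y * y, x * z * z, y * z * z,
        x * y * z,
        x * x, y * y, z * z,
        x * y, x * z, y * z,
        x, y, z,
        np.full_like(x, alpha),
    ]
    return np.vstack(cols)


def fit_nonlinearity(
    y_camera: Sequence[float], y_spectrometer: Sequence[float]
) -> dict:
    """Polynomial fits (orders 1-3) of spectrometer Y on camera Y.

    Returns ``{1: {"coefficients": ..., "r2": ...}, 2: ..., 3: ...,
    "best_order": int}``.  With constant targets the total variance is zero
    and R^2 is reported as 0 for every order (documented convention).
    """
    y_cam = np.asarray(y_camera, dtype=float)
    y_spec = np.asarray(y_spectrometer, dtype=float)
    if y_cam.shape != y_spec.shape or y_cam.ndim != 1:
        raise ValidationError("gray-level sequences must be 1-d and paired")
    if y_cam.size < 4:
        raise InsufficientDataError("cubic fit needs at least 4 gray levels")
    if np.any(y_cam <= 0) or np.any(y_spec <= 0):
        raise ValidationError("gray-level Y values must be positive")

    ss_tot = float(np.sum((y_spec - y_spec.mean()) ** 2))
    report: dict = {}
    for order in (1, 2, 3):
        coef = np.polyfit(y_cam, y_spec, order)
        resid = y_spec - np.polyval(coef, y_cam)
        ss_res = float(np.sum(resid**2))
        r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        report[order] = {"coefficients": coef.tolist(), "r2": r2}
    report["best_order"] = max((1, 2, 3), key=lambda o: report[o]["r2"])
    return report


@dataclass
class CalibrationModel:
    """Fitted 3 x 20 correction matrix with its diagnostic report."""

    C: np.ndarray
    alpha: float = 1.0
    nonlinearity_report: dict | None = None
    n_patches: int = 0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (3, len(VARIABLE_TERMS)):
            raise ValidationError("C must be 3 x 20")
        if not np.all(np.isfinite(self.C)):
            raise ValidationError("C must be finite")

    def to_json(self, path) -> None:
        payload = {
            "C": self.C.tolist(),
            "alpha": self.alpha,
            "nonlinearity_report": self.nonlinearity_report,
            "n_patches": self.n_patches,
            "terms": list(VARIABLE_TERMS),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            payload = json.load(fh)
        report = payload.get("nonlinearity_report")
        if report is not None:
            report = {int(k) if k.isdigit() else k: v for k, v in report.items()}
        return cls(
            np.array(payload["C"]),
            alpha=payload["alpha"],
            nonlinearity_report=report,
            n_patches=payload.get("n_patches", 0),
        )


def fit_correction_matrix(
    xyz_camera,
    xyz_spectrometer,
    alpha: float = 1.0,
    gray_patches: Sequence[int] = DEFAULT_GRAY_PATCHES,
    pinv_rtol: float = PINV_RTOL,
) -> CalibrationModel:
    """Fit C = [XYZ_spectrometer] @ pinv(V) over paired checker patches.

    Accepts lists of :class:`TristimulusXYZ` (provenance is then checked:
    camera on the first argument, spectrometer on the second) or plain
    (n, 3) arrays.  ``gray_patches`` gives the 1-based indices of the
    neutral ramp used for the diagnostic nonlinearity report; indices
    outside the patch range simply skip the report.
    """
    cam = _as_xyz_rows(xyz_camera, expected_provenance="camera")
    spec = _as_xyz_rows(xyz_spectrometer, expected_provenance="spectrometer")
    if cam.shape != spec.shape:
        raise ValidationError("camera and spectrometer patch counts differ")
    n = cam.shape[0]
    if n < len(VARIABLE_TERMS):
        raise InsufficientDataError(
            f"need at least {len(VARIABLE_TERMS)} patches, got {n}"
        )

    V = expand_variable_matrix(cam, alpha=alpha)  # 20 x n
    C = spec.T @ np.linalg.pinv(V, rcond=pinv_rtol)

    report = None
    idx = np.asarray(gray_patches, dtype=int) - 1
    if idx.size >= 4 and np.all((idx >= 0) & (idx < n)):
        y_cam, y_spec = cam[idx, 1], spec[idx, 1]
        if np.all(y_cam > 0) and np.all(y_spec > 0):
            report = fit_nonlinearity(y_cam, y_spec)
    return CalibrationModel(C, alpha=alpha, nonlinearity_report=report, n_patches=n)


def apply_correction(
    model: CalibrationModel, xyz_camera: TristimulusXYZ
) -> TristimulusXYZ:
    """Corrected XYZ = C @ V(camera XYZ); provenance becomes 'corrected'."""
    if isinstance(xyz_camera, TristimulusXYZ) and xyz_camera.provenance != "camera":
        raise ProvenanceError(
            f"apply_correction expects camera XYZ, got {xyz_camera.provenance!r}"
        )
    v = expand_variable_vector(xyz_camera, alpha=model.alpha)
    out = model.C @ v
    return TristimulusXYZ(*map(float, out), provenance="corrected")


def apply_correction_array(model: CalibrationModel, xyz_rows: np.ndarray) -> np.ndarray:
    """Vectorised correction: (n, 3) camera XYZ rows -> (n, 3) corrected rows."""
    V = expand_variable_matrix(xyz_rows, alpha=model.alpha)
    return (model.C @ V).T


def _as_xyz_row(xyz) -> tuple[float, float, float]:
    if isinstance(xyz, TristimulusXYZ):
        return xyz.X, xyz.Y, xyz.Z
    x, y, z = (float(v) for v in xyz)
    return x, y, z


def _as_xyz_rows(values, expected_provenance: str | None = None) -> np.ndarray:
    if isinstance(values, np.ndarray):
        arr = np.atleast_2d(np.asarray(values, dtype=float))
        if arr.shape[1] != 3:
            raise ValidationError("xyz array must be n x 3")
        return arr
    rows = []
    for item in values:
        if isinstance(item, TristimulusXYZ):
            if expected_provenance and item.provenance != expected_provenance:
                raise ProvenanceError(
                    f"expected {expected_provenance!r} XYZ, got {item.provenance!r}"
                )
            rows.append([item.X, item.Y, item.Z])
        else:
            rows.append([float(v) for v in item])
    return np.asarray(rows, dtype=float)
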