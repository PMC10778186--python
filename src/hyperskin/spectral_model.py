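"""PCA spectral basis and XYZ-to-spectrum reconstruction.

The reflectance spectra of the 24 checker patches are decomposed by PCA
into a mean spectrum and an orthonormal 401 x 12 component matrix EV; 12
components capture essentially all the variance of smooth natural-object
reflectances.  A transformation matrix M then regresses the PCA scores on
the 7-term colour polynomial

    V_color = [XYZ  XY  YZ  XZ  X  Y  Z]^T

built from the spectrometer XYZ of the same patches:

    M = scores^T @ pinv(V_color)            (12 x 7)

and a single corrected camera XYZ is expanded to a full spectrum as

    S = mean + EV @ (M @ V_color(XYZ_corrected)).

PCA here is mean-centred with an explicit mean add-back at reconstruction;
an uncentred mode (no mean, components straight from the data SVD) is
available via ``center=False`` for comparison.  With centred PCA the score
vectors are *affine*, not linear, functions of XYZ, so V_color is extended
with a constant intercept term whenever the basis is centred (without it
the reconstruction carries a systematic colour bias of several CIEDE2000
units); the intercept can be forced on or off explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import PINV_RTOL, CalibrationModel, apply_correction_array
from .cie_color import (
    N_BANDS,
    CMFSet,
    LabColor,
    Spectrum,
    TristimulusXYZ,
    ciede2000,
    load_cmf,
    rmse_spectra,
    spectra_to_xyz_array,
    srgb_to_xyz_array,
    xyz_to_lab,
)
from .errors import (
    InsufficientDataError,
    ModelIncompleteError,
    ProvenanceError,
    ValidationError,
)

V_COLOR_TERMS = ("XYZ", "XY", "YZ", "XZ", "X", "Y", "Z")


def v_color_vector(
    xyz: TristimulusXYZ | Sequence[float], include_constant: bool = False
) -> np.ndarray:
    """The 7-term colour polynomial of one XYZ triple (8 terms with intercept)."""
    if isinstance(xyz, TristimulusXYZ):
        x, y, z = xyz.X, xyz.Y, xyz.Z
    else:
        x, y, z = (float(v) for v in xyz)
    terms = [x * y * z, x * y, y * z, x * z, x, y, z]
    if include_constant:
        terms.append(1.0)
    return np.array(terms)


def v_color_matrix(xyz_rows: np.ndarray, include_constant: bool = False) -> np.ndarray:
    """Vectorised colour polynomial: (n, 3) XYZ rows -> (7 or 8) x n."""
    arr = np.atleast_2d(np.asarray(xyz_rows, dtype=float))
    if arr.shape[1] != 3:
        raise ValidationError("xyz rows must be n x 3")
    x, y, z = arr[:, 0], arr[:, 1], arr[:, 2]
    cols = [x * y * z, x * y, y * z, x * z, x, y, z]
    if include_constant:
        cols.append(np.ones_like(x))
    return np.vstack(cols)


@dataclass
class SpectralBasis:
    """PCA basis of checker reflectances plus the XYZ-to-score map M."""

    mean_spectrum: np.ndarray
    EV: np.ndarray  # 401 x n_components, orthonormal columns
    scores: np.ndarray  # n_train x n_components
    explained_variance_cumulative: np.ndarray
    M: np.ndarray | None = None
    centered: bool = True
    include_constant: bool = False

    def __post_init__(self) -> None:
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        self.EV = np.asarray(self.EV, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.explained_variance_cumulative = np.asarray(
            self.explained_variance_cumulative, dtype=float
        )
        if self.mean_spectrum.shape != (N_BANDS,):
            raise ValidationError("mean spectrum must have 401 samples")
        if self.EV.ndim != 2 or self.EV.shape[0] != N_BANDS:
            raise ValidationError("EV must be 401 x n_components")
        if self.M is not None:
            self.M = np.asarray(self.M, dtype=float)

    @property
    def n_components(self) -> int:
        return self.EV.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "mean_spectrum": self.mean_spectrum.tolist(),
            "EV": self.EV.tolist(),
            "scores": self.scores.tolist(),
            "explained_variance_cumulative": self.explained_variance_cumulative.tolist(),
            "M": None if self.M is None else self.M.tolist(),
            "centered": self.centered,
            "include_constant": self.include_constant,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SpectralBasis":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            np.array(p["mean_spectrum"]),
            np.array(p["EV"]),
            np.array(p["scores"]),
            np.array(p["explained_variance_cumulative"]),
            M=None if p["M"] is None else np.array(p["M"]),
            centered=p["centered"],
            include_constant=p["include_constant"],
        )


def fit_spectral_basis(
    spectra: Sequence[Spectrum],
    n_components: int = 12,
    center: bool = True,
    variance_threshold: float | None = None,
    include_constant: bool | None = None,
) -> SpectralBasis:
    """Fit the PCA basis of a set of reflectance spectra (M left unset).

    Components come from the SVD of the (optionally mean-centred) data
    matrix, ordered by decreasing variance; scores are the projections of
    the training data onto the components.  With ``variance_threshold`` the
    component count becomes the smallest one whose cumulative explained
    variance reaches the threshold (capped at ``n_components``).

    ``include_constant`` controls the intercept term of V_color used later
    by :func:`fit_transformation_matrix`; by default it tracks ``center``
    (an affine score/XYZ relation needs an intercept).
    """
    X = np.vstack([sp.values for sp in spectra])  # n x 401
    n = X.shape[0]
    if n < n_components + 1:
        raise InsufficientDataError(
            f"need at least {n_components + 1} spectra for {n_components} components"
        )
    mean = X.mean(axis=0) if center else np.zeros(N_BANDS)
    Xc = X - mean
    total_var = float(np.sum(Xc * Xc))
    if total_var == 0.0:
        raise InsufficientDataError("spectra are identical; PCA is degenerate")

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ratios = (s * s) / total_var
    cumulative = np.cumsum(ratios)

    k = n_components
    if variance_threshold is not None:
        reached = np.flatnonzero(cumulative >= variance_threshold)
        k = int(reached[0]) + 1 if reached.size else min(n_components, s.size)
        k = min(k, n_components)
    k = min(k, s.size)

    EV = Vt[:k].T  # 401 x k
    scores = Xc @ EV  # n x k
    return SpectralBasis(
        mean_spectrum=mean,
        EV=EV,
        scores=scores,
        explained_variance_cumulative=cumulative[:k],
        centered=center,
        include_constant=center if include_constant is None else include_constant,
    )


def fit_transformation_matrix(
    basis: SpectralBasis,
    xyz_spectrometer,
    pinv_rtol: float = PINV_RTOL,
) -> SpectralBasis:
    """Fit M = scores^T @ pinv(V_color) from the spectrometer XYZ of the
    training patches; returns the basis with M attached."""
    xyz_rows = _xyz_rows(xyz_spectrometer)
    if xyz_rows.shape[0] != basis.scores.shape[0]:
        raise ValidationError("XYZ count must match the training score count")
    Vc = v_color_matrix(xyz_rows, include_constant=basis.include_constant)
    M = basis.scores.T @ np.linalg.pinv(Vc, rcond=pinv_rtol)
    basis.M = M
    return basis


def reconstruct_spectrum(
    basis: SpectralBasis, xyz_corrected: TristimulusXYZ
) -> Spectrum:
    """Expand one corrected XYZ into a 401-sample reflectance spectrum."""
    if basis.M is None:
        raise ModelIncompleteError("basis has no transformation matrix M")
    if (
        isinstance(xyz_corrected, TristimulusXYZ)
        and xyz_corrected.provenance != "corrected"
    ):
        raise ProvenanceError(
            f"reconstruction expects corrected XYZ, got {xyz_corrected.provenance!r}"
        )
    vc = v_color_vector(xyz_corrected, include_constant=basis.include_constant)
    values = basis.mean_spectrum + basis.EV @ (basis.M @ vc)
    return Spectrum(values, kind="reconstructed")


def reconstruct_spectra_array(basis: SpectralBasis, xyz_rows: np.ndarray) -> np.ndarray:
    """Vectorised reconstruction: (n, 3) corrected XYZ rows -> (n, 401)."""
    if basis.M is None:
        raise ModelIncompleteError("basis has no transformation matrix M")
    Vc = v_color_matrix(xyz_rows, include_constant=basis.include_constant)
    return basis.mean_spectrum + (basis.EV @ (basis.M @ Vc)).T


@dataclass
class CheckerEvalReport:
    """Per-patch and mean RMSE / CIEDE2000 of the reconstruction pipeline."""

    per_patch_rmse: np.ndarray
    mean_rmse: float
    per_patch_de2000: np.ndarray
    mean_de2000: float
    lab_pairs: list  # (measured LabColor, simulated LabColor) per patch

    def to_json(self, path) -> None:
        payload = {
            "per_patch_rmse": self.per_patch_rmse.tolist(),
            "mean_rmse": self.mean_rmse,
            "per_patch_de2000": self.per_patch_de2000.tolist(),
            "mean_de2000": self.mean_de2000,
            "lab_pairs": [
                {"measured": list(m.as_array()), "simulated": list(s.as_array())}
                for m, s in self.lab_pairs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def evaluate_colorchecker(
    calib: CalibrationModel,
    basis: SpectralBasis,
    checker_rgb: np.ndarray,
    checker_spectra: Sequence[Spectrum],
    S: Spectrum,
    cmf: CMFSet | None = None,
) -> CheckerEvalReport:
    """Run the full per-patch pipeline and score it against measurements.

    For each patch: decode the camera RGB to XYZ, apply the correction
    matrix, reconstruct the spectrum, and compare with the measured
    spectrum by RMSE (on unclipped values) and by CIEDE2000 after both
    spectra are integrated to Lab under the session illuminant.
    """
    rgb = np.atleast_2d(np.asarray(checker_rgb, dtype=float))
    spectra = list(checker_spectra)
    if rgb.shape[0] != len(spectra):
        raise ValidationError("RGB rows and measured spectra must pair up")
    if cmf is None:
        cmf = load_cmf()

    cam_xyz = srgb_to_xyz_array(rgb)
    corrected = apply_correction_array(calib, cam_xyz)
    recon = reconstruct_spectra_array(basis, corrected)

    measured = np.vstack([sp.values for sp in spectra])
    diffs = recon - measured
    per_rmse = np.sqrt(np.mean(diffs * diffs, axis=1))

    meas_xyz = spectra_to_xyz_array(measured, S, cmf)
    sim_xyz = spectra_to_xyz_array(recon, S, cmf)
    from .cie_color import spectrum_to_xyz  # whitepoint of the session illuminant

    _, wp = spectrum_to_xyz(Spectrum.flat(1.0), S, cmf)
    lab_pairs = []
    per_de = np.empty(len(spectra))
    for i in range(len(spectra)):
        lab_m = xyz_to_lab(TristimulusXYZ(*meas_xyz[i]), wp)
        lab_s = xyz_to_lab(TristimulusXYZ(*sim_xyz[i]), wp)
        lab_pairs.append((lab_m, lab_s))
        per_de[i] = ciede2000(lab_m, lab_s)

    return CheckerEvalReport(
        per_patch_rmse=per_rmse,
        mean_rmse=float(per_rmse.mean()),
        per_patch_de2000=per_de,
        mean_de2000=float(per_de.mean()),
        lab_pairs=lab_pairs,
    )


def _xyz_rows(values) -> np.ndarray:
    if isinstance(values, np.ndarray):
        return np.atleast_2d(np.asarray(values, dtype=float))
    rows = []
    for item in values:
        if isinstance(item, TristimulusXYZ):
            rows.append([item.X, item.Y, item.Z])
        else:
            rows.append([float(v) for v in item])
    return np.asarray(rows, dtype=float)
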