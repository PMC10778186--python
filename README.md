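# hyperskin

Reconstructing per-pixel visible spectra (380–780 nm, 1 nm) from ordinary
RGB photographs, for the differential analysis of skin lesions — in
particular separating early mycosis fungoides (MF, a cutaneous T-cell
lymphoma) from the visually confusable inflammatory conditions psoriasis
(PsO) and atopic dermatitis (AD), plus normal skin. The package is aimed
at researchers in spectral imaging and computational dermatology who have
a consumer camera, a spectrometer, and a standard 24-patch colour checker.

## Method

**Camera/spectrometer cross-calibration.** Both instruments observe the
same 24-patch checker. Spectrometer reflectances R(λ) are integrated to
CIE XYZ under the session illuminant S(λ):

    X = k Σ S(λ) R(λ) x̄(λ) Δλ,   k = 100 / Σ S(λ) ȳ(λ) Δλ,

so the illuminant's Y is pinned to 100. Camera sRGB values are decoded
(IEC 61966-2-1) to camera XYZ. The camera's error sources — a cubic tone
nonlinearity (diagnosed on the six-patch neutral gray ramp by nested
polynomial regression), dark current, and chrominance noise coupling the
channels — are absorbed by a 3×20 correction matrix **C** fitted by
Moore–Penrose pseudoinverse over the 20-term polynomial expansion
V = [X³ Y³ Z³ X²Y … X Y Z α]ᵀ of each camera XYZ:

    C = [XYZ_spectrometer] · pinv(V),   XYZ_corrected = C · V.

**Spectral reconstruction.** PCA of the 24 measured patch spectra gives a
mean spectrum and a 401×12 orthonormal basis EV (12 components carry
≈ 99.99 % of the variance). A 12-term-by-colour-term transformation matrix
**M** regresses the PCA scores on the colour polynomial
V_color = [XYZ XY YZ XZ X Y Z]ᵀ (plus an intercept when the PCA is
centred), and a single corrected XYZ expands to a full spectrum:

    S = mean + EV · (M · V_color(XYZ_corrected)).

Fidelity is scored per patch by spectral RMSE and by CIEDE2000 after both
spectra are integrated back to L\*a\*b\*.

**Lesion analysis.** A stand-in segmenter (CIELAB a\* threshold at
median + c·MAD with binary morphology; external mask PNGs are equally
accepted) delineates the lesion; each pixel of the region becomes a
reconstructed spectrum; the region's 12 PCA-score distributions are
summarised into a 60-dim feature vector; an XGBoost ensemble classifies
MF / PsO / AD / normal, evaluated by patient-grouped k-fold
cross-validation (no patient in both train and test) with macro
one-vs-rest sensitivity, specificity, F1 and ROC-AUC.

Since clinical images cannot be redistributed, `hyperskin.synthetic_data`
generates every input: smooth low-dimensional reflectance spectra, a
parametric camera forward model, checker scenes, and 4-class lesion image
datasets with truth masks and patient grouping.

## Worked example

```python
from hyperskin import (
    CameraModel, generate_checker_scene, fit_correction_matrix,
    fit_spectral_basis, fit_transformation_matrix, evaluate_colorchecker,
    SceneSpec, generate_lesion_dataset, run_cross_validation,
)
from hyperskin.cie_color import srgb_to_xyz_array
from hyperskin.classify import samples_from_dataset

# a synthetic checker session shot by a camera with a cubic tone curve,
# dark offset and chrominance noise
scene = generate_checker_scene(seed=0, cam=CameraModel())
cam_xyz = srgb_to_xyz_array(scene.camera_rgb.astype(float))
calib = fit_correction_matrix(cam_xyz, scene.true_xyz)

basis = fit_spectral_basis(scene.spectra, n_components=12)
basis = fit_transformation_matrix(basis, scene.true_xyz)
report = evaluate_colorchecker(calib, basis, scene.camera_rgb,
                               scene.spectra, scene.illuminant)

dataset = generate_lesion_dataset(SceneSpec(seed=0))   # 20 patients x 10 images
samples = samples_from_dataset(dataset, calib, basis)
cv = run_cross_validation(samples, k=5, seed=0)
```

Output:

```
nonlinearity best order: 3
cubic fit R^2: 1.00000
12-component cumulative variance: 1.000000
mean spectral RMSE: 0.0239
mean CIEDE2000:     0.61
5-fold grouped CV: sensitivity 95.00%, specificity 98.33%, F1 95.03%, ROC-AUC 0.9912
```

The gray-ramp diagnostic correctly identifies the camera's cubic
nonlinearity; 12 principal components capture the full variance of the
synthetic patch set; reconstructed patch spectra sit within 0.024 RMS of
the measured ones and within 0.61 CIEDE2000 units (≈ half a just-noticeable
difference) of their colours; and the grouped cross-validation separates
the four lesion classes with macro ROC-AUC 0.99 at the generator's default
spectral separation.

A `hyperskin` console command exposes the same workflow
(`simulate`, `calibrate`, `reconstruct`, `evaluate-checker`, `segment`,
`classify-cv`); run `hyperskin --help`.

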