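# Methods

This note documents the models, numerical choices and known limitations of
`hyperskin`, in the package's own terms.

## Colorimetric kernel

All spectra live on the fixed grid 380–780 nm at 1 nm (401 samples).
Tristimulus integration uses a plain 1 nm Riemann sum; at this tabulation
the difference from trapezoid or finer quadrature is below 2·10⁻³ relative
(verified against a 0.1 nm trapezoid oracle in the tests), far inside every
tolerance used downstream. The brightness ratio k normalises the
illuminant's Y to exactly 100, so all XYZ live on the Y ∈ [0, 100] scale
and the L\*a\*b\* whitepoint is always the session illuminant itself
(never a hard-coded D65).

The CIE 1931 2° observer table bundled in `data/cie1931_cmf_2deg.csv` is
tabulated from the multi-lobe Gaussian analytic fit of Wyman, Sloan &
Shirley (*JCGT* 2013), accurate to roughly 1 % of peak, with the small
negative excursion of the x̄ fit clipped to zero. The same table is used
on the camera and the spectrometer side of the pipeline, so every
cross-instrument comparison is self-consistent; absolute colorimetry
against an external instrument would need the officially tabulated
observer instead.

sRGB decoding applies the IEC 61966-2-1 inverse companding before the
linear sRGB/D65 matrix. The camera pipeline being calibrated presumably
wrote gamma-encoded images; decoding the *known* standard curve first
leaves the correction matrix free to absorb only the residual, device-
specific nonlinearity. This is an assumption — cameras vary in their
actual encoding — and it is the single most consequential unverifiable
choice in the pipeline.

CIEDE2000 follows the standard Sharma–Wu–Dalal formulation with
kL = kC = kH = 1, and is cross-checked against scikit-image's independent
implementation to 10⁻⁴ in the test suite.

## Error-correction model

The 20-term variable vector V (cubic, quadratic, cross and linear
monomials of camera XYZ plus the dark constant α) is fixed in the
documented order. α ≡ 1: the paper-style dark current enters as a learned
intercept — the last column of C — which is an equivalent parameterisation
that removes one free input. The pseudoinverse truncates singular values
below 10⁻¹⁰ of the largest (configurable), which silently yields the
minimum-norm solution for rank-deficient patch sets; C itself is therefore
not unique, but its *predictions* on the fitted span are, and only those
are contracted by the tests.

The gray-ramp nonlinearity analysis (orders 1–3 OLS of spectrometer Y on
camera Y over patches 19–24) is diagnostic only: it documents why cubic
terms belong in V. R² is defined as 0 when the target variance is zero.
Note the fit direction is *spectrometer on camera*; the inverse of a cubic
tone curve is not itself a polynomial, so R² of the cubic fit is near — not
exactly — 1 even for an exactly cubic camera.

## Spectral basis and reconstruction

PCA of the 24 patch reflectances is mean-centred with the mean added back
at reconstruction. The transformation matrix M regresses the scores on the
7-term colour polynomial V_color = [XYZ XY YZ XZ X Y Z]ᵀ. Because centred
scores are an *affine* function of XYZ, V_color is automatically extended
with a constant intercept term whenever the basis is centred: without it
the reconstruction carries a systematic colour bias that we measured at
≈ 3.9 mean CIEDE2000 units on the synthetic checker (vs ≈ 0.1 with the
intercept). An uncentred mode (`center=False`: no mean term anywhere, a
homogeneous linear model) performs equivalently on the synthetic checker
and is retained for comparison; the centred+intercept default is preferred
because its mean term makes near-mean reconstructions robust when M is
poorly conditioned.

M is fitted from the *spectrometer* XYZ of the training patches but
applied to *corrected* camera XYZ. The asymmetry is intentional and kept
as-is; after a good correction the two agree to within the correction
residual.

Reconstructed reflectances may slightly over/undershoot [0, 1]; the
`Spectrum.clipped()` helper clips to [0, 1.2] for display, but RMSE is
always evaluated on unclipped values — clipping would bias the error
metric downwards.

## Synthetic data: what it emulates, what it does not

**Reflectance spectra** are a flat baseline plus 3–6 bands drawn from a
fixed dictionary of nine broad Gaussians (σ = 55 nm) whose per-band weight
scales decay steeply. The decay is deliberate: empirically, natural-object
and checker reflectances concentrate their variance in a handful of smooth
modes, and the feasibility of XYZ→spectrum regression rests entirely on
that concentration. A flat eigenvalue profile (iid band weights) makes the
family strongly metameric and the reconstruction problem ill-posed
regardless of implementation quality. The 24-draw set therefore has
effective linear dimension well below 12, matching the compactness that a
12-component basis presumes.

**Illuminant**: a 5500 K Planckian radiator, peak-normalised — a smooth
broadband stand-in for an unspecified stable studio source. All results
are conditioned on it.

**Camera forward model**: monotone polynomial tone curve applied
per-channel to XYZ/100 (default 0.85v + 0.10v² + 0.05v³), dark offset
added to all channels (default 1 Y-unit, i.e. 1 % of white), zero-mean
Gaussian chrominance noise on X and Z (default σ = 0.5), then sRGB
encoding with 8-bit quantisation. With the identity camera the encode/
decode round-trip is exact up to quantisation and gamut clipping.

**Checker scene**: patches 1–18 chromatic draws, patches 19–24 a strictly
descending neutral ramp at classic checker densities (0.88 … 0.031).

**Lesion datasets**: each patient carries one class and an individual skin
brightness; skin is a melanin-slope spectrum with haemoglobin dips at
542/577 nm; lesions are elliptical regions whose spectra modulate the skin
by class-specific absorption profiles (MF: strong 550 nm erythema plus a
595 nm shoulder; PsO: moderate erythema plus long-wavelength brightening,
mimicking silvery scale; AD: milder, blue-shifted erythema), all scaled by
a single `separation` parameter. Images add a smooth illumination gradient
and pixel noise, rendered through the same camera model as the checker.
Defaults: 20 patients × 10 images at 64×64, equal class proportions,
separation 1.0 — sizes chosen so the full pipeline runs in seconds while
keeping ≥ 4 patients per class in 5-fold grouping.

What passing tests on this data do **not** show: real lesions are not
elliptical, not spectrally homogeneous, and not two-material mixtures;
real skin optics (scattering, phototype variation, specularities, hair)
and real camera spectral sensitivities are absent. The synthetic results
demonstrate internal consistency and correct mechanics of the pipeline,
not clinical performance.

## Segmentation stand-in

The deep segmentation model that fills this role in practice is valuable
through its trained weights, which are inseparable from private clinical
data; the pipeline's requirement is only a *coarse* lesion/skin split. The
stand-in thresholds the CIELAB a\* channel at median + 3·MAD, then applies
morphological opening and closing (radius 2). It emits its pre-threshold
statistic through a logistic squash as a probability map so cross-entropy
is computable. Known failure mode: when a lesion dominates the frame the
robust threshold chases it; the `absolute_threshold` parameter and the
external-mask path cover that case. Empty ∩ empty masks score dice = IoU
= 1 by convention.

## Classification

One sample per image. Features: per-pixel PCA scores of the reconstructed
spectra inside the mask, summarised per component by mean, SD and
10/50/90th percentiles (12 × 5 = 60 features). Normal-skin images, having
no lesion, fall back to a centred elliptical region. XGBoost defaults
(300 trees, depth 4, η = 0.1, subsample 0.9, fixed seed) are artifact
decisions, not tuned values. Folding is patient-grouped with near-equal
patient counts and a seeded shuffle; macro one-vs-rest metrics are
reported both pooled over folds (headline) and as mean-of-folds, since
either convention is defensible. A fold that lacks a class skips that
class's fold-level AUC; the pooled aggregate is unaffected.

## Problem sizes

Default test and demonstration sizes — 24-patch scenes, 5-seed batches,
200-image datasets at 64×64, k ∈ {3, 5} — keep any single check within
seconds on one CPU while leaving every headline margin wide (e.g.
reconstruction RMSE ≈ 0.02 against a 0.05 budget; grouped ROC-AUC ≈ 0.99
against 0.95).
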