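import numpy as np
import pytest
from sklearn.decomposition import PCA

from hyperskin.cie_color import (
    N_BANDS,
    WAVELENGTHS_NM,
    Spectrum,
    TristimulusXYZ,
    ciede2000,
    srgb_to_xyz_array,
)
from hyperskin.errors import (
    InsufficientDataError,
    ModelIncompleteError,
    ProvenanceError,
    ValidationError,
)
from hyperskin.calibration import fit_correction_matrix
from hyperskin.spectral_model import (
    SpectralBasis,
    evaluate_colorchecker,
    fit_spectral_basis,
    fit_transformation_matrix,
    reconstruct_spectrum,
    v_color_matrix,
    v_color_vector,
)
from hyperskin.synthetic_data import (
    CameraModel,
    generate_checker_scene,
    generate_reflectance_spectra,
    load_checker_lab_reference,
)

from conftest import calibrate_scene


def _smooth(rng):
    centers = rng.uniform(420, 740, 2)
    return [np.exp(-0.5 * ((WAVELENGTHS_NM - c) / 60.0) ** 2) for c in centers]


class TestFitSpectralBasis:
    def test_identical_spectra_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_spectral_basis([Spectrum.flat(0.5)] * 24, n_components=12)

    def test_too_few_spectra_rejected(self):
        spectra = generate_reflectance_spectra(12, seed=1)
        with pytest.raises(InsufficientDataError):
            fit_spectral_basis(spectra, n_components=12)

    def test_rank_two_family_fully_explained_by_two_components(self, rng):
        b1, b2 = _smooth(rng)
        spectra = [
            Spectrum(np.clip(0.3 + w1 * b1 + w2 * b2, 0, 1.2), kind="reconstructed")
            for w1, w2 in rng.uniform(0.05, 0.4, size=(24, 2))
        ]
        basis = fit_spectral_basis(spectra, n_components=2)
        assert basis.explained_variance_cumulative[1] == pytest.approx(1.0, abs=1e-9)

    def test_generator_spectra_low_dimensional(self):
        spectra = generate_reflectance_spectra(24, seed=0)
        basis = fit_spectral_basis(spectra, n_components=12)
        assert basis.explained_variance_cumulative[-1] >= 0.999

    def test_orthonormal_components(self):
        basis = fit_spectral_basis(generate_reflectance_spectra(24, seed=0), 12)
        gram = basis.EV.T @ basis.EV
        assert np.allclose(gram, np.eye(12), atol=1e-8)

    def test_full_rank_reconstruction_of_training_data(self):
        spectra = generate_reflectance_spectra(24, seed=3)
        basis = fit_spectral_basis(spectra, n_components=23)
        X = np.vstack([sp.values for sp in spectra])
        recon = basis.mean_spectrum + basis.scores @ basis.EV.T
        assert np.max(np.abs(recon - X)) <= 1e-8

    def test_truncation_error_nonincreasing_in_components(self):
        spectra = generate_reflectance_spectra(24, seed=4)
        X = np.vstack([sp.values for sp in spectra])
        errs = []
        for k in (2, 4, 8, 12, 16):
            basis = fit_spectral_basis(spectra, n_components=k)
            recon = basis.mean_spectrum + basis.scores @ basis.EV.T
            errs.append(np.sqrt(np.mean((recon - X) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_matches_sklearn_pca_oracle(self):
        spectra = generate_reflectance_spectra(24, seed=5)
        X = np.vstack([sp.values for sp in spectra])
        basis = fit_spectral_basis(spectra, n_components=6)
        ref = PCA(n_components=6).fit(X)
        # components agree up to sign; explained variance exactly
        for j in range(6):
            dot = abs(float(ref.components_[j] @ basis.EV[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(
            np.cumsum(ref.explained_variance_ratio_),
            basis.explained_variance_cumulative,
            atol=1e-10,
        )

    def test_variance_threshold_mode(self):
        spectra = generate_reflectance_spectra(24, seed=0)
        basis = fit_spectral_basis(spectra, n_components=12, variance_threshold=0.99)
        assert basis.n_components <= 12
        assert basis.explained_variance_cumulative[-1] >= 0.99


class TestTransformationMatrix:
    def test_generate_and_recover(self, rng):
        spectra = generate_reflectance_spectra(24, seed=6)
        basis = fit_spectral_basis(spectra, 12)
        xyz = rng.uniform(5, 95, size=(24, 3))
        M_true = rng.normal(0, 1, size=(12, basis.scores.shape[1]))
        # overwrite scores with targets exactly linear in V_color
        Vc = v_color_matrix(xyz, include_constant=basis.include_constant)
        basis.scores = (M_true[:, : Vc.shape[0]] @ Vc).T
        basis = fit_transformation_matrix(basis, xyz)
        pred = (basis.M @ Vc).T
        assert np.max(np.abs(pred - basis.scores)) <= 1e-8

    def test_zero_scores_give_zero_M(self, rng):
        spectra = generate_reflectance_spectra(24, seed=7)
        basis = fit_spectral_basis(spectra, 12)
        basis.scores = np.zeros_like(basis.scores)
        basis = fit_transformation_matrix(basis, rng.uniform(5, 95, (24, 3)))
        assert np.allclose(basis.M, 0.0)

    def test_duplicated_column_minimum_norm(self, rng):
        spectra = generate_reflectance_spectra(24, seed=8)
        basis = fit_spectral_basis(spectra, 12)
        xyz = rng.uniform(5, 95, size=(24, 3))
        xyz[1] = xyz[0]
        basis.scores[1] = basis.scores[0]
        basis = fit_transformation_matrix(basis, xyz)
        Vc = v_color_matrix(xyz, include_constant=basis.include_constant)
        pred = (basis.M @ Vc).T
        assert np.allclose(pred[0], pred[1])

    def test_misaligned_counts_rejected(self, rng):
        basis = fit_spectral_basis(generate_reflectance_spectra(24, seed=9), 12)
        with pytest.raises(ValidationError):
            fit_transformation_matrix(basis, rng.uniform(5, 95, (23, 3)))


class TestReconstruction:
    def test_missing_M_rejected(self):
        basis = fit_spectral_basis(generate_reflectance_spectra(24, seed=0), 12)
        with pytest.raises(ModelIncompleteError):
            reconstruct_spectrum(basis, TristimulusXYZ(1, 2, 3, provenance="corrected"))

    def test_wrong_provenance_rejected(self):
        basis = fit_spectral_basis(generate_reflectance_spectra(24, seed=0), 12)
        basis.M = np.zeros((12, 8))
        with pytest.raises(ProvenanceError):
            reconstruct_spectrum(basis, TristimulusXYZ(1, 2, 3, provenance="camera"))

    def test_zero_M_returns_mean_spectrum(self):
        basis = fit_spectral_basis(generate_reflectance_spectra(24, seed=0), 12)
        n_terms = 8 if basis.include_constant else 7
        basis.M = np.zeros((12, n_terms))
        sp = reconstruct_spectrum(basis, TristimulusXYZ(30, 40, 50, provenance="corrected"))
        assert sp.kind == "reconstructed"
        assert np.allclose(sp.values, basis.mean_spectrum)

    def test_constructed_consistent_family_exact_recovery(self, rng):
        # family built so spectra are exactly mean + EV @ (M_true @ V_color)
        EV = np.linalg.qr(rng.normal(0, 1, (N_BANDS, 12)))[0]
        mean = 0.4 + 0.1 * np.sin(WAVELENGTHS_NM / 80.0)
        M_true = rng.normal(0, 0.02, (12, 7))
        xyz = rng.uniform(2, 8, size=(24, 3))
        Vc = v_color_matrix(xyz)  # 7 x 24
        X = mean + (EV @ (M_true @ Vc)).T
        spectra = [Spectrum(row, kind="reconstructed") for row in X]
        basis = fit_spectral_basis(spectra, n_components=12)
        basis = fit_transformation_matrix(basis, xyz)
        for i in (0, 11, 23):
            sp = reconstruct_spectrum(
                basis, TristimulusXYZ(*xyz[i], provenance="corrected")
            )
            assert np.max(np.abs(sp.values - X[i])) <= 1e-6

    def test_training_roundtrip_on_ideal_scene(self, ideal_scene, ideal_calibration):
        from hyperskin.cie_color import rmse_spectra
        from hyperskin.calibration import apply_correction_array

        calib, basis = ideal_calibration
        cam_xyz = srgb_to_xyz_array(ideal_scene.camera_rgb.astype(float))
        corrected = apply_correction_array(calib, cam_xyz)
        for i in (0, 5, 20):
            sp = reconstruct_spectrum(
                basis, TristimulusXYZ(*corrected[i], provenance="corrected")
            )
            assert rmse_spectra(sp, ideal_scene.spectra[i]) <= 0.05


class TestEvaluateColorchecker:
    def test_ideal_camera_accuracy(self, ideal_scene, ideal_calibration, cmf):
        calib, basis = ideal_calibration
        rep = evaluate_colorchecker(
            calib, basis, ideal_scene.camera_rgb, ideal_scene.spectra,
            ideal_scene.illuminant, cmf,
        )
        assert rep.mean_rmse <= 0.05
        assert rep.mean_de2000 <= 1.0

    def test_means_are_arithmetic_means(self, ideal_scene, ideal_calibration, cmf):
        calib, basis = ideal_calibration
        rep = evaluate_colorchecker(
            calib, basis, ideal_scene.camera_rgb, ideal_scene.spectra,
            ideal_scene.illuminant, cmf,
        )
        assert rep.mean_rmse == pytest.approx(rep.per_patch_rmse.mean())
        assert rep.mean_de2000 == pytest.approx(rep.per_patch_de2000.mean())

    def test_rmse_nondecreasing_in_camera_noise(self, cmf):
        means = []
        for sd in (0.0, 0.25, 0.5, 1.0):
            per_seed = []
            for seed in range(5):
                scene = generate_checker_scene(
                    seed=seed, cam=CameraModel(chroma_noise_sd=sd), cmf=cmf
                )
                calib, basis = calibrate_scene(scene)
                rep = evaluate_colorchecker(
                    calib, basis, scene.camera_rgb, scene.spectra,
                    scene.illuminant, cmf,
                )
                per_seed.append(rep.mean_rmse)
            means.append(np.mean(per_seed))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_mismatched_counts_rejected(self, ideal_scene, ideal_calibration):
        calib, basis = ideal_calibration
        with pytest.raises(ValidationError):
            evaluate_colorchecker(
                calib, basis, ideal_scene.camera_rgb[:23], ideal_scene.spectra,
                ideal_scene.illuminant,
            )


class TestCheckerLabReference:
    def test_reported_color_differences_reproduce(self):
        table = load_checker_lab_reference()
        computed = [
            ciede2000(
                (row.L_measured, row.a_measured, row.b_measured),
                (row.L_simulated, row.a_simulated, row.b_simulated),
            )
            for row in table.itertuples()
        ]
        assert np.max(np.abs(np.array(computed) - table.de2000_reported)) <= 0.02
        assert round(float(np.mean(computed)), 2) == 0.28


class TestSerialization:
    def test_json_round_trip(self, tmp_path, ideal_calibration):
        _, basis = ideal_calibration
        path = tmp_path / "basis.json"
        basis.to_json(path)
        loaded = SpectralBasis.from_json(path)
        assert np.allclose(loaded.EV, basis.EV)
        assert np.allclose(loaded.M, basis.M)
        assert loaded.centered == basis.centered
        assert loaded.include_constant == basis.include_constant
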