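"""NNLS solver, design matrix, pixelwise unmixing, display scaling."""

import numpy as np
import pytest

from hyperunmix import (
    CoefficientMaps,
    HyperStack,
    NoiseModel,
    UnmixConfig,
    ValidationError,
    build_design_matrix,
    calibrate_stack,
    forward_simulate,
    generate_phantom,
    load_coefficient_maps,
    measure_reference_envelope,
    nnls_solve,
    normalize_basis,
    ROIMask,
    save_coefficient_maps,
    scale_coefficient_maps,
    simulate_reference_well,
    unmix_stack,
)
from conftest import brute_force_nnls


class TestNnlsSolve:
    def test_identity_design_recovers_rhs(self):
        x, r2 = nnls_solve(np.eye(4), np.array([1.0, 2.0, 0.0, 3.0]))
        np.testing.assert_allclose(x, [1, 2, 0, 3])
        assert r2 == pytest.approx(0.0, abs=1e-14)

    def test_negative_rhs_forces_zero_coefficient(self):
        A = np.array([[1.0], [1.0]])
        x, r2 = nnls_solve(A, np.array([-1.0, -1.0]))
        np.testing.assert_allclose(x, [0.0])
        assert r2 == pytest.approx(2.0)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValidationError):
            nnls_solve(np.array([[np.nan]]), np.array([1.0]))
        with pytest.raises(ValidationError):
            nnls_solve(np.array([[1.0]]), np.array([np.inf]))

    def test_matches_exhaustive_active_set_oracle(self):
        """Seeded 86x4 instances with mixed-sign observations."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            A = np.abs(rng.standard_normal((86, 4)))
            b = rng.standard_normal(86)
            x, r2 = nnls_solve(A, b)
            x_o, r2_o = brute_force_nnls(A, b)
            assert abs(r2 - r2_o) < 1e-8
            assert (x >= 0).all()

    def test_oracle_equivalence_k5(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            A = rng.random((20, 5))
            b = rng.standard_normal(20)
            _, r2 = nnls_solve(A, b)
            _, r2_o = brute_force_nnls(A, b)
            assert abs(r2 - r2_o) < 1e-8

    def test_kkt_conditions_hold_at_solution(self):
        """Active coefficients have ~zero gradient; zero ones non-negative."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            A = np.abs(rng.standard_normal((86, 4)))
            b = rng.standard_normal(86)
            x, _ = nnls_solve(A, b)
            grad = A.T @ (A @ x - b)
            tol = 1e-6 * np.linalg.norm(A.T @ b)
            assert (np.abs(grad[x > 0]) < tol).all()
            assert (grad[x == 0] >= -tol).all()


class TestDesignMatrix:
    def test_shape_is_nex_times_bands_by_components(self, norm_basis):
        A = build_design_matrix(norm_basis, UnmixConfig())
        assert A.shape == (43 * 2, 4)

    def test_single_band_single_component_column_is_spectrum(self, norm_basis):
        cfg = UnmixConfig(bands_used=("blue",), components=("collagen",))
        A = build_design_matrix(norm_basis, cfg)
        np.testing.assert_array_equal(A[:, 0], norm_basis["collagen"].band_column("blue"))

    def test_component_permutation_permutes_columns(self, norm_basis):
        A = build_design_matrix(norm_basis, UnmixConfig(components=norm_basis.labels))
        perm = norm_basis.labels[::-1]
        B = build_design_matrix(norm_basis, UnmixConfig(components=perm))
        np.testing.assert_array_equal(B, A[:, ::-1])

    def test_unnormalized_basis_rejected_with_hint(self, basis):
        with pytest.raises(ValidationError, match="normalize_basis"):
            build_design_matrix(basis, UnmixConfig())

    def test_missing_band_rejected(self, norm_basis):
        with pytest.raises(ValidationError):
            build_design_matrix(norm_basis, UnmixConfig(bands_used=("ultraviolet",)))


class TestUnmixStack:
    def test_exact_mixture_recovers_coefficients_and_zero_residual(
        self, norm_basis
    ):
        scene = generate_phantom("checkerboard", (32, 32), norm_basis, seed=0)
        # random positive mixture on top of the blocks
        rng = np.random.default_rng(2)
        scene.concentration_maps += 0.2 * rng.random(scene.concentration_maps.shape)
        stack = forward_simulate(scene, norm_basis)
        maps, residual = unmix_stack(stack, norm_basis)
        np.testing.assert_allclose(
            maps.coeffs, scene.concentration_maps, atol=1e-8
        )
        np.testing.assert_allclose(residual.values, 0.0, atol=1e-16)

    def test_pure_component_argmax_matches_label_everywhere(self, norm_basis):
        scene = generate_phantom("checkerboard", (64, 64), norm_basis, seed=1)
        stack = forward_simulate(scene, norm_basis)
        maps, _ = unmix_stack(stack, norm_basis)
        pure = scene.pure_mask()
        truth = scene.concentration_maps.argmax(axis=2)[pure]
        got = maps.coeffs.argmax(axis=2)[pure]
        assert (truth == got).all()

    def test_noisy_phantom_recovery_correlates(self, basis, norm_basis):
        scene = generate_phantom("crypts", (96, 96), basis, seed=0)
        stack = forward_simulate(
            scene, basis, noise=NoiseModel("poisson", 100), seed=0
        )
        maps, _ = unmix_stack(stack, norm_basis)
        for j, label in enumerate(scene.labels):
            t = scene.concentration_maps[:, :, j].ravel()
            m = maps.coeffs[:, :, j].ravel()
            assert np.corrcoef(m, t)[0, 1] >= 0.95

    def test_all_zero_pixel_gives_zero_coefficients_and_residual(
        self, axis, bands, norm_basis
    ):
        data = np.zeros((2, 2, len(axis), len(bands)))
        data[0, 0] = 1.0
        stack = HyperStack(data=data, excitation=axis, emission=bands)
        maps, residual = unmix_stack(stack, norm_basis)
        np.testing.assert_array_equal(maps.coeffs[1, 1], 0.0)
        assert residual.values[1, 1] == 0.0

    def test_linearity_in_stack_intensity(self, norm_basis):
        scene = generate_phantom("checkerboard", (32, 32), norm_basis, seed=3)
        stack = forward_simulate(scene, norm_basis)
        alpha = 3.7
        scaled = HyperStack(
            data=alpha * stack.data,
            excitation=stack.excitation,
            emission=stack.emission,
            meta=stack.meta,
        )
        m1, _ = unmix_stack(stack, norm_basis)
        m2, _ = unmix_stack(scaled, norm_basis)
        np.testing.assert_allclose(m2.coeffs, alpha * m1.coeffs, rtol=1e-8, atol=1e-12)

    def test_axis_mismatch_rejected(self, norm_basis, bands):
        from hyperunmix import ExcitationAxis

        other = ExcitationAxis(np.arange(720.0, 925.0, 5.0))
        data = np.ones((4, 4, len(other), len(bands)))
        stack = HyperStack(data=data, excitation=other, emission=bands)
        with pytest.raises(ValidationError):
            unmix_stack(stack, norm_basis)

    def test_calibration_state_mismatch_refused(self, axis, bands, norm_basis):
        scene = generate_phantom("checkerboard", (32, 32), norm_basis, seed=0)
        stack = forward_simulate(scene, norm_basis)
        K = 2.0 + np.sin(axis.wavelengths_nm / 30.0)
        well = simulate_reference_well(axis, bands, K, shape=(8, 8))
        profile = measure_reference_envelope(well, ROIMask.full((8, 8)))
        calibrated = calibrate_stack(stack, profile)
        with pytest.raises(ValidationError, match="calibration"):
            unmix_stack(calibrated, norm_basis)

    def test_out_of_model_component_increases_residual(self, axis, bands, norm_basis):
        """A positive fifth signature not in the basis strictly adds misfit."""
        scene = generate_phantom("checkerboard", (32, 32), norm_basis, seed=0)
        stack = forward_simulate(scene, norm_basis)
        intruder = np.exp(-0.5 * ((axis.wavelengths_nm - 850) / 20.0) ** 2)
        extra = np.zeros_like(stack.data)
        extra[:, :, :, bands.index("blue")] = 0.5 * intruder
        extra[:, :, :, bands.index("green")] = 0.3 * intruder
        polluted = HyperStack(
            data=stack.data + extra, excitation=axis, emission=bands, meta=stack.meta
        )
        _, r_clean = unmix_stack(stack, norm_basis)
        _, r_polluted = unmix_stack(polluted, norm_basis)
        assert r_polluted.values.sum() > r_clean.values.sum()
        assert r_polluted.values.sum() > 0

    def test_pixel_order_independence_via_transpose(self, norm_basis):
        scene = generate_phantom("crypts", (64, 64), norm_basis.map(lambda s: s), seed=0)
        stack = forward_simulate(scene, norm_basis, noise=NoiseModel("poisson", 500), seed=0)
        maps, _ = unmix_stack(stack, norm_basis)
        transposed = HyperStack(
            data=np.ascontiguousarray(stack.data.transpose(1, 0, 2, 3)),
            excitation=stack.excitation,
            emission=stack.emission,
            meta=stack.meta,
        )
        maps_t, _ = unmix_stack(transposed, norm_basis)
        np.testing.assert_allclose(
            maps_t.coeffs.transpose(1, 0, 2), maps.coeffs, rtol=1e-10, atol=1e-12
        )


class TestFreeBandAmplitude:
    def test_recovers_mixture_under_band_attenuation(self, axis, bands, norm_basis):
        """A damped green channel fits exactly once its multiplier is free."""
        scene = generate_phantom("checkerboard", (32, 32), norm_basis, seed=0)
        stack = forward_simulate(scene, norm_basis)
        damped = stack.data.copy()
        damped[:, :, :, bands.index("green")] *= 0.6
        stack_d = HyperStack(data=damped, excitation=axis, emission=bands, meta=stack.meta)
        cfg = UnmixConfig(free_band_amplitude=True)
        maps, residual = unmix_stack(stack_d, norm_basis, cfg)
        # alternation stops once the residual decrease drops below 1e-8
        assert residual.values.max() < 1e-6
        np.testing.assert_allclose(maps.coeffs, scene.concentration_maps, atol=1e-4)

    def test_residual_never_worse_than_fixed_bands(self, axis, bands, norm_basis):
        scene = generate_phantom("checkerboard", (32, 32), norm_basis, seed=1)
        stack = forward_simulate(scene, norm_basis, noise=NoiseModel("poisson", 200), seed=1)
        _, r_fixed = unmix_stack(stack, norm_basis)
        _, r_free = unmix_stack(stack, norm_basis, UnmixConfig(free_band_amplitude=True))
        assert r_free.values.sum() <= r_fixed.values.sum() + 1e-9


class TestScaling:
    def make_maps(self):
        coeffs = np.zeros((2, 2, 2))
        coeffs[:, :, 0] = [[4.0, 2.0], [1.0, 0.0]]  # epithelium, max 4
        coeffs[:, :, 1] = [[2.0, 1.0], [0.5, 0.0]]  # collagen
        return CoefficientMaps(coeffs=coeffs, labels=("epithelium", "collagen"))

    def test_reference_max_becomes_one(self):
        maps = scale_coefficient_maps(self.make_maps())
        assert maps.component("epithelium").max() == pytest.approx(1.0)
        assert maps.component("collagen")[0, 0] == pytest.approx(0.5)
        assert maps.max_values["epithelium"] == pytest.approx(1.0)
        assert maps.max_values["collagen"] == pytest.approx(0.5)
        assert maps.scaled

    def test_idempotent(self):
        once = scale_coefficient_maps(self.make_maps())
        twice = scale_coefficient_maps(once)
        np.testing.assert_allclose(twice.coeffs, once.coeffs)

    def test_pixelwise_ratios_preserved(self):
        raw = self.make_maps()
        scaled = scale_coefficient_maps(raw)
        nz = raw.coeffs[:, :, 1] > 0
        np.testing.assert_allclose(
            scaled.coeffs[:, :, 0][nz] / scaled.coeffs[:, :, 1][nz],
            raw.coeffs[:, :, 0][nz] / raw.coeffs[:, :, 1][nz],
        )

    def test_all_zero_reference_rejected_with_suggestion(self):
        coeffs = np.zeros((2, 2, 2))
        coeffs[:, :, 1] = 1.0
        maps = CoefficientMaps(coeffs=coeffs, labels=("epithelium", "collagen"))
        with pytest.raises(ValidationError, match="display_reference"):
            scale_coefficient_maps(maps)


class TestMapsDiskFormat:
    def test_round_trip_with_residual(self, tmp_path, norm_basis):
        scene = generate_phantom("checkerboard", (32, 32), norm_basis, seed=0)
        stack = forward_simulate(scene, norm_basis)
        maps, residual = unmix_stack(stack, norm_basis)
        maps = scale_coefficient_maps(maps)
        save_coefficient_maps(maps, residual, tmp_path / "c.tif")
        back, res_back = load_coefficient_maps(tmp_path / "c.tif")
        assert back.labels == maps.labels
        assert back.scaled
        np.testing.assert_allclose(back.coeffs, maps.coeffs, rtol=1e-6, atol=1e-7)
        np.testing.assert_allclose(res_back.values, residual.values, atol=1e-6)
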