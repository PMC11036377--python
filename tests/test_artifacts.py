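"""Bias field, noise, gamma and k-space motion simulation."""

import numpy as np
import pytest
from scipy import stats

from neosynth.artifacts import (BiasFieldParams, MotionParams,
                                MotionTrajectory, NoiseParams, apply_bias,
                                apply_gamma, apply_motion, apply_noise,
                                bias_field, polynomial_exponents,
                                sample_bias_field, sample_log_gamma,
                                sample_motion_params, sample_noise,
                                sample_trajectory)
from neosynth.core import Image


class TestBiasField:
    def test_zero_coefficients_identity(self, rng):
        img = Image(rng.random((16, 16, 16)))
        params = BiasFieldParams(np.zeros(len(polynomial_exponents(3))))
        out = apply_bias(img, params)
        assert np.allclose(out.voxels, img.voxels)

    def test_log_ratio_refits_order3_polynomial(self, rng):
        """log(output/input) must be an order-3 polynomial: refit it by
        least squares and check the residual (oracle)."""
        img = Image(np.full((12, 12, 12), 2.0))
        params = sample_bias_field(rng)
        out = apply_bias(img, params)
        log_ratio = np.log(out.voxels / img.voxels)
        exps = polynomial_exponents(3)
        axes = [np.linspace(-1, 1, n) for n in img.shape]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        design = np.stack([(X ** a) * (Y ** b) * (Z ** c)
                           for a, b, c in exps], axis=-1).reshape(-1,
                                                                  len(exps))
        coeffs, *_ = np.linalg.lstsq(design, log_ratio.ravel(), rcond=None)
        residual = design @ coeffs - log_ratio.ravel()
        assert np.abs(residual).max() < 1e-6
        assert np.allclose(coeffs, params.coefficients, atol=1e-8)

    def test_field_bounded_by_coefficient_budget(self, rng):
        params = sample_bias_field(rng, max_magnitude=0.5)
        n_monomials = len(polynomial_exponents(3))
        field = bias_field(params, (10, 10, 10))
        assert field.min() >= np.exp(-0.5 * n_monomials) - 1e-12
        assert field.max() <= np.exp(0.5 * n_monomials) + 1e-12
        assert field.min() > 0

    def test_crop_commutes_in_shared_frame(self, rng):
        """Evaluating the field on a crop with the parent frame equals
        cropping the parent field."""
        params = sample_bias_field(rng)
        full = bias_field(params, (16, 16, 16))
        crop = bias_field(params, (8, 8, 8),
                          frame=(np.array([4, 4, 4]), (16, 16, 16)))
        assert np.allclose(crop, full[4:12, 4:12, 4:12])


class TestNoise:
    def test_sampled_std_range(self, rng):
        for _ in range(500):
            assert 5e-3 <= sample_noise(rng).std <= 0.1

    def test_empirical_std_matches(self, rng):
        params = sample_noise(rng)
        img = Image(np.zeros((64, 64, 64)))
        out = apply_noise(img, params, rng)
        assert np.std(out.voxels - img.voxels) == pytest.approx(
            params.std, rel=0.03)

    def test_zero_std_identity(self, rng):
        img = Image(rng.random((8, 8, 8)))
        out = apply_noise(img, NoiseParams(std=0.0), rng)
        assert np.array_equal(out.voxels, img.voxels)

    def test_zero_mean(self, rng):
        img = Image(np.zeros((32, 32, 32)))
        params = NoiseParams(std=0.05)
        out = apply_noise(img, params, rng)
        se = params.std / np.sqrt(out.voxels.size)
        assert abs(out.voxels.mean()) < 3 * se


class TestGamma:
    def test_zero_log_gamma_identity(self, rng):
        img = Image(rng.random((8, 8, 8)))
        assert np.allclose(apply_gamma(img, 0.0).voxels, img.voxels)

    def test_power_law_value(self):
        img = Image(np.full((2, 2, 2), 0.25))
        out = apply_gamma(img, np.log(2.0))  # gamma = 2
        assert np.allclose(out.voxels, 0.0625)

    def test_monotone_for_any_gamma(self, rng):
        img = Image(np.sort(rng.random(27)).reshape(3, 3, 3))
        for log_gamma in (-0.3, -0.1, 0.2, 0.3):
            out = apply_gamma(img, log_gamma)
            assert np.all(np.diff(out.voxels.ravel()) >= 0)

    def test_negative_input_rejected(self):
        img = Image(np.array([[[-0.1, 0.5]]]))
        with pytest.raises(ValueError, match="non-negative"):
            apply_gamma(img, 0.1)

    def test_sampler_range(self, rng):
        draws = [sample_log_gamma(rng) for _ in range(200)]
        assert all(-0.3 <= g <= 0.3 for g in draws)


class TestTrajectory:
    def test_peak_amplitudes_match_sampled_maxima(self, rng):
        for _ in range(50):
            params = sample_motion_params(rng)
            assert 3.0 <= params.max_translation_mm <= 8.0
            assert 3.0 <= params.max_rotation_deg <= 8.0
            traj = sample_trajectory(params, 40, rng)
            assert traj.peak_translation() == pytest.approx(
                params.max_translation_mm, rel=1e-9)
            assert traj.peak_rotation() == pytest.approx(
                params.max_rotation_deg, rel=1e-9)

    def test_event_time_uniform(self, rng):
        """First-movement segment is uniform over the acquisition
        (chi-square goodness of fit at alpha = 0.01)."""
        n_segments = 20
        params = MotionParams(5.0, 5.0)
        events = [sample_trajectory(params, n_segments, rng).event_segment
                  for _ in range(10_000)]
        counts = np.bincount(events, minlength=n_segments)
        chi2 = stats.chisquare(counts).pvalue
        assert chi2 > 0.01

    def test_reproducible(self):
        params = MotionParams(4.0, 6.0)
        a = sample_trajectory(params, 32, np.random.default_rng(8))
        b = sample_trajectory(params, 32, np.random.default_rng(8))
        assert np.array_equal(a.translations_mm, b.translations_mm)
        assert np.array_equal(a.rotations_deg, b.rotations_deg)

    def test_step_shape(self, rng):
        traj = sample_trajectory(MotionParams(5.0, 5.0), 30, rng)
        norms = np.linalg.norm(traj.translations_mm, axis=1)
        e = traj.event_segment
        assert np.all(norms[:e] == 0)
        assert norms[-1] == pytest.approx(5.0)
        assert np.all(np.diff(norms) >= -1e-9)  # ramp then plateau


class TestApplyMotion:
    def _object(self, rng, n=32):
        vox = np.zeros((n, n, n))
        vox[8:24, 10:22, 12:20] = 1.0
        vox += 0.1 * rng.random((n, n, n))
        vox[:4] = 0
        return Image(vox)

    def test_identity_trajectory_roundtrip(self, rng):
        img = self._object(rng)
        traj = MotionTrajectory.identity(img.shape[1])
        out = apply_motion(img, traj)
        assert np.abs(out.voxels - img.voxels).max() < 1e-6

    def test_constant_integer_translation_equals_roll(self, rng):
        """All segments sharing one integer-voxel translation reduce to the
        Fourier shift theorem: compare against np.roll (oracle)."""
        img = self._object(rng)
        t = (3.0, -2.0, 4.0)
        traj = MotionTrajectory.constant(img.shape[1], translation_mm=t)
        out = apply_motion(img, traj)
        expected = np.roll(img.voxels, shift=[int(v) for v in t],
                           axis=(0, 1, 2))
        nrmse = (np.sqrt(np.mean((out.voxels - expected) ** 2))
                 / (expected.max() - expected.min()))
        assert nrmse < 1e-3

    def test_subvoxel_translation_matches_sinc_shift(self, rng):
        """Sub-voxel constant translation agrees with an independent
        spectral sinc-shift computed directly with np.fft."""
        img = self._object(rng)
        t = (0.5, -1.25, 0.75)
        traj = MotionTrajectory.constant(img.shape[1], translation_mm=t)
        out = apply_motion(img, traj)
        F = np.fft.fftn(img.voxels)
        for d, shift in enumerate(t):
            k = np.fft.fftfreq(img.shape[d])
            shape = [1, 1, 1]
            shape[d] = img.shape[d]
            F = F * np.exp(-2j * np.pi * k * shift).reshape(shape)
        expected = np.abs(np.fft.ifftn(F))
        nrmse = (np.sqrt(np.mean((out.voxels - expected) ** 2))
                 / (expected.max() - expected.min()))
        assert nrmse < 1e-3

    def test_energy_preserved_for_pure_translation(self, rng):
        """Phase ramps are unitary: total energy is conserved for any
        pure-translation trajectory (Parseval)."""
        img = self._object(rng)
        params = MotionParams(6.0, 6.0)
        traj = sample_trajectory(params, img.shape[1], rng)
        traj = MotionTrajectory(traj.translations_mm,
                                np.zeros_like(traj.rotations_deg))
        out = apply_motion(img, traj)
        e_in = np.sum(img.voxels ** 2)
        e_out = np.sum(out.voxels ** 2)
        assert abs(e_out - e_in) / e_in < 1e-6

    def test_severity_monotone_in_amplitude(self, rng):
        """Mean absolute deviation from the clean image grows with the
        translation amplitude at fixed trajectory shape."""
        img = self._object(rng)
        n = img.shape[1]
        base = sample_trajectory(MotionParams(1.0, 1.0), n,
                                 np.random.default_rng(4))
        mads = []
        for amp in (1.0, 3.0, 6.0):
            traj = MotionTrajectory(base.translations_mm * amp,
                                    np.zeros((n, 3)))
            out = apply_motion(img, traj)
            mads.append(np.abs(out.voxels - img.voxels).mean())
        assert mads[0] < mads[1] < mads[2]

    def test_background_forced_to_zero(self, rng):
        img = self._object(rng)
        mask = np.zeros(img.shape, bool)
        mask[:8] = True
        traj = MotionTrajectory.identity(img.shape[1])
        out = apply_motion(img, traj, background_mask=mask)
        assert np.abs(out.voxels[mask]).max() < 1e-6

    def test_trajectory_length_mismatch_rejected(self, rng):
        img = self._object(rng)
        traj = MotionTrajectory.identity(img.shape[1] + 5)
        with pytest.raises(ValueError, match="does not match"):
            apply_motion(img, traj)

    def test_rotation_mixes_kspace(self, rng):
        img = self._object(rng)
        traj = sample_trajectory(MotionParams(5.0, 7.0), img.shape[1],
                                 rng)
        out = apply_motion(img, traj)
        assert out.voxels.shape == img.voxels.shape
        assert np.all(np.isfinite(out.voxels))
        assert np.abs(out.voxels - img.voxels).mean() > 1e-4
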