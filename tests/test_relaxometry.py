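"""Schedules, masking, recentering and the per-pixel decay fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gelfront as gf
from gelfront.phantom import NoiseModel, render_parameter_maps, simulate_acquisition
from gelfront.relaxometry import (
    AcquisitionSchedule,
    ImageStack,
    fit_blip_pixel,
    fit_inversion_recovery_pixel,
    fit_monoexp_pixel,
    fit_parameter_maps,
    make_signal_mask,
    recenter_stack,
    rician_bias_correct,
)

from _helpers import oracle_blip, oracle_monoexp, uniform_disc_spec


class TestSchedules:
    def test_default_grids_match_protocol(self):
        msme = AcquisitionSchedule.msme()
        blip = AcquisitionSchedule.blip()
        fisp = AcquisitionSchedule.fisp()
        assert len(msme) == 32 and msme.times[0] == 6.5 and msme.times[-1] == 208.0
        assert blip.times == tuple(float(t) for t in range(3, 13))
        assert len(fisp) == 40 and fisp.times[0] == 400.0
        assert np.allclose(np.diff(fisp.times_ms), 160.0)

    @pytest.mark.parametrize(
        "times", [(), (0.0, 1.0), (3.0, 2.0), (1.0, 1.0), (-1.0, 2.0)]
    )
    def test_invalid_time_grids_rejected(self, times):
        with pytest.raises(ValueError):
            AcquisitionSchedule("MSME", times)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSchedule("RARE", (1.0, 2.0))

    def test_stack_schedule_length_must_match(self):
        with pytest.raises(ValueError):
            ImageStack(np.zeros((5, 8, 8)), AcquisitionSchedule.blip())

    def test_negative_intensities_rejected(self):
        data = np.zeros((10, 8, 8))
        data[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            ImageStack(data, AcquisitionSchedule.blip())


class TestMask:
    def _disc_stack(self, amplitude=6.0, sigma=0.0, seed=0, grid=(96, 96)):
        maps = render_parameter_maps(uniform_disc_spec(a_s=amplitude / 3, a_l=2 * amplitude / 3, grid=grid))
        return maps, simulate_acquisition(maps, AcquisitionSchedule.blip(), NoiseModel(sigma=sigma, seed=seed))

    def test_pure_noise_gives_empty_mask(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(
            np.abs(rng.normal(0, 0.1, (10, 64, 64))), AcquisitionSchedule.blip()
        )
        with pytest.warns(UserWarning, match="degenerate"):
            mask = make_signal_mask(stack)
        assert not mask.any()

    def test_noiseless_disc_recovered_exactly(self):
        maps, stack = self._disc_stack(sigma=0.0)
        mask = make_signal_mask(stack)
        assert np.array_equal(mask, maps.mask)

    def test_noisy_disc_area_within_two_percent(self):
        maps, stack = self._disc_stack(sigma=0.1, seed=4)
        mask = make_signal_mask(stack)
        assert mask.sum() == pytest.approx(maps.mask.sum(), rel=0.02)


class TestRecenter:
    def _offset_stack(self, dr, dc, grid=64):
        img = np.zeros((grid, grid))
        rr, cc = np.indices((grid, grid))
        disc = np.hypot(rr - (grid // 2 + dr), cc - (grid // 2 + dc)) < 12
        img[disc] = 6.0
        stack = ImageStack(img[None], AcquisitionSchedule.blip(n_echoes=1))
        return stack, disc

    def test_centered_disc_identity(self):
        stack, mask = self._offset_stack(0, 0)
        _, _, shift = recenter_stack(stack, mask)
        assert shift == (0, 0)

    def test_known_offset_recovered(self):
        stack, mask = self._offset_stack(3, -2)
        moved, new_mask, shift = recenter_stack(stack, mask)
        assert shift == (-3, 2)
        centered, _ = self._offset_stack(0, 0)
        assert np.array_equal(moved.data, centered.data)

    @given(dr=st.integers(-8, 8), dc=st.integers(-8, 8))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_idempotent(self, dr, dc):
        stack, mask = self._offset_stack(dr, dc)
        moved, new_mask, _ = recenter_stack(stack, mask)
        _, _, second = recenter_stack(moved, new_mask)
        assert second == (0, 0)

    def test_empty_mask_rejected(self):
        stack, _ = self._offset_stack(0, 0)
        with pytest.raises(ValueError):
            recenter_stack(stack, np.zeros(stack.grid_shape, dtype=bool))


class TestMonoexpFit:
    times = AcquisitionSchedule.msme().times_ms

    def test_forward_inverse_identity(self):
        y = 6.0 * np.exp(-self.times / 100.0)
        fit = fit_monoexp_pixel(y, self.times)
        assert fit.converged
        assert fit.s0 == pytest.approx(6.0, rel=1e-6)
        assert fit.t2l == pytest.approx(100.0, rel=1e-6)

    def test_constant_series_flagged(self):
        fit = fit_monoexp_pixel(np.full_like(self.times, 2.5), self.times)
        assert not fit.converged

    def test_all_zero_flagged(self):
        fit = fit_monoexp_pixel(np.zeros_like(self.times), self.times)
        assert not fit.converged
        assert np.isnan(fit.s0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_monoexp_pixel(np.array([1.0, 0.5]), np.array([1.0, 2.0]))

    def test_noisy_recovery_median_error(self):
        """200 replicate pixels at sigma=0.1: median |t2l error| < 10 ms."""
        rng = np.random.default_rng(1)
        truth = 6.0 * np.exp(-self.times / 100.0)
        errors = []
        for _ in range(200):
            y = np.hypot(truth + rng.normal(0, 0.1, truth.shape), rng.normal(0, 0.1, truth.shape))
            fit = fit_monoexp_pixel(y, self.times)
            if fit.converged:
                errors.append(abs(fit.t2l - 100.0))
        assert len(errors) > 150
        assert np.median(errors) < 10.0

    def test_matches_exhaustive_search(self):
        """Noiseless instances: LM fit equals the 0.01 ms grid search."""
        rng = np.random.default_rng(7)
        grid = np.arange(5.0, 500.0 + 1e-9, 0.01)
        for _ in range(20):
            s0, t2l = rng.uniform(1, 8), rng.uniform(20, 400)
            y = s0 * np.exp(-self.times / t2l)
            fit = fit_monoexp_pixel(y, self.times)
            o_s0, o_t2l = oracle_monoexp(y, self.times, grid)
            assert abs(fit.t2l - o_t2l) <= 0.01
            assert abs(fit.s0 - o_s0) <= 0.01


class TestBlipFit:
    times = AcquisitionSchedule.blip().times_ms

    def test_pure_baseline(self):
        fit = fit_blip_pixel(np.full_like(self.times, 4.0), self.times)
        assert fit.a_l == pytest.approx(4.0, abs=1e-6)
        assert fit.a_s == pytest.approx(0.0, abs=1e-6)

    def test_forward_inverse_identity(self):
        y = 1.8 * np.exp(-self.times / 3.6)
        fit = fit_blip_pixel(y, self.times)
        assert fit.converged
        assert fit.a_s == pytest.approx(1.8, rel=1e-6)
        assert fit.t2s == pytest.approx(3.6, rel=1e-6)
        assert fit.a_l == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_flagged(self):
        fit = fit_blip_pixel(np.zeros_like(self.times), self.times)
        assert not fit.converged

    def test_matches_exhaustive_search(self):
        """20 random noiseless instances vs 0.01 ms grid in T2S with exact amplitudes."""
        rng = np.random.default_rng(21)
        grid = np.arange(1.0, 20.0 + 1e-9, 0.01)
        for _ in range(20):
            a_s, t2s, a_l = rng.uniform(0.5, 8), rng.uniform(1.5, 15), rng.uniform(0, 6)
            y = a_s * np.exp(-self.times / t2s) + a_l
            fit = fit_blip_pixel(y, self.times)
            o_as, o_t2s, o_al = oracle_blip(y, self.times, grid)
            assert abs(fit.t2s - o_t2s) <= 0.01
            assert abs(fit.a_s - o_as) <= 0.02
            assert abs(fit.a_l - o_al) <= 0.02


class TestInversionRecoveryFit:
    tis = AcquisitionSchedule.fisp().times_ms

    def test_forward_inverse_identity(self):
        y = np.abs(6.0 * (1 - 2 * np.exp(-self.tis / 500.0)))
        fit = fit_inversion_recovery_pixel(y, self.tis)
        assert fit.converged
        assert fit.t1 == pytest.approx(500.0, rel=1e-6)
        assert fit.s0 == pytest.approx(6.0, rel=1e-6)

    def test_zero_signal_flagged(self):
        fit = fit_inversion_recovery_pixel(np.zeros_like(self.tis), self.tis)
        assert not fit.converged
        assert np.isnan(fit.t1)

    def test_noisy_recovery_median_error(self):
        """200 replicates at sigma=0.1, T1=800 ms: median |error| < 80 ms."""
        rng = np.random.default_rng(2)
        truth = np.abs(6.0 * (1 - 2 * np.exp(-self.tis / 800.0)))
        errors = []
        for _ in range(200):
            y = np.hypot(truth + rng.normal(0, 0.1, truth.shape), rng.normal(0, 0.1, truth.shape))
            fit = fit_inversion_recovery_pixel(y, self.tis)
            if fit.converged:
                errors.append(abs(fit.t1 - 800.0))
        assert len(errors) > 150
        assert np.median(errors) < 80.0


class TestParameterMaps:
    def test_total_amplitude_identity_exact(self, study_1h_low_noise):
        maps = study_1h_low_noise.maps
        m = maps.mask
        assert m.any()
        assert np.array_equal(maps.a_t[m], maps.a_s[m] + maps.a_l[m])
        assert np.all(np.isnan(maps.a_t[~m]))

    def test_empty_mask_gives_all_flagged_maps(self):
        maps_gt = render_parameter_maps(uniform_disc_spec(grid=(48, 48), radius=2.0))
        blip = simulate_acquisition(maps_gt, AcquisitionSchedule.blip(), NoiseModel(sigma=0.0))
        msme = simulate_acquisition(maps_gt, AcquisitionSchedule.msme(), NoiseModel(sigma=0.0))
        maps = fit_parameter_maps(msme, blip, mask=np.zeros((48, 48), dtype=bool))
        assert not maps.mask.any()
        assert np.all(np.isnan(maps.a_t))

    def test_grid_mismatch_rejected(self):
        small = render_parameter_maps(uniform_disc_spec(grid=(32, 32), radius=1.5))
        big = render_parameter_maps(uniform_disc_spec(grid=(48, 48), radius=1.5))
        blip = simulate_acquisition(small, AcquisitionSchedule.blip(), NoiseModel(sigma=0.0))
        msme = simulate_acquisition(big, AcquisitionSchedule.msme(), NoiseModel(sigma=0.0))
        with pytest.raises(ValueError, match="grid mismatch"):
            fit_parameter_maps(msme, blip)

    def test_gel_median_recovery_within_five_percent(self, study_1h_low_noise):
        """In-gel median fitted a_t within 5% of ground truth at sigma=0.1."""
        from gelfront.phantom import pixel_radii

        result = study_1h_low_noise
        spec = result.spec
        # ground-truth gel annulus in recentered coordinates
        maps = result.maps
        rr, cc = np.indices(maps.grid_shape)
        radius = np.hypot(rr - maps.center[0], cc - maps.center[1]) * maps.pixel_size
        gel = (
            (radius > spec.region_boundaries["interface2"] + 0.2)
            & (radius < spec.region_boundaries["gel"] - 0.2)
            & maps.mask
        )
        assert gel.sum() > 100
        truth = 6.0  # preset gel total amplitude
        assert np.nanmedian(maps.a_t[gel]) == pytest.approx(truth, rel=0.05)

    def test_recovery_bias_and_rmse_vs_noise(self):
        """Bias vanishes as noise -> 0; RMSE grows monotonically with noise."""
        times = AcquisitionSchedule.blip().times_ms
        truth = 1.8 * np.exp(-times / 3.6) + 4.5  # crossing-layer-like pixel
        biases, rmses = [], []
        for sigma in (0.0, 0.05, 0.6):
            rng = np.random.default_rng(17)
            estimates = []
            for _ in range(150):
                y = np.hypot(truth + rng.normal(0, sigma, 10), rng.normal(0, sigma, 10))
                fit = fit_blip_pixel(y, times)
                if fit.converged:
                    estimates.append(fit.a_s + fit.a_l)
                if sigma == 0.0:
                    break  # deterministic
            est = np.array(estimates)
            biases.append(abs(np.median(est) - 6.3))
            rmses.append(np.sqrt(np.mean((est - 6.3) ** 2)))
        assert biases[0] < 1e-6
        assert biases[0] <= biases[2] + 1e-9
        assert rmses[0] <= rmses[1] <= rmses[2]

    def test_short_t2_core_invisible_to_long_te_sequence(self):
        """A sub-ms-T2 core is detected by the 3 ms first echo but not the 6.5 ms one."""
        spec = gf.build_phantom_spec(
            1.0, "HPMC400", overrides={"core": {"a_s": 20.0, "t2s": 0.8}}, grid_shape=(96, 96)
        )
        maps = render_parameter_maps(spec)
        noise = NoiseModel(sigma=0.05, seed=9)
        blip = simulate_acquisition(maps, AcquisitionSchedule.blip(), noise)
        msme = simulate_acquisition(maps, AcquisitionSchedule.msme(), NoiseModel(sigma=0.05, seed=10))
        blip_mask = make_signal_mask(blip, k_sigma=4, keep_largest=False, fill_holes=False)
        msme_mask = make_signal_mask(msme, k_sigma=4, keep_largest=False, fill_holes=False)
        from gelfront.phantom import pixel_radii

        core = pixel_radii(spec) < spec.region_boundaries["core"] - 0.1
        assert blip_mask[core].mean() > 0.9  # core hydration visible at 3 ms
        assert msme_mask[core].mean() < 0.05  # and gone by 6.5 ms
        assert blip_mask.sum() > msme_mask.sum()

    def test_bias_correction_restores_background_toward_zero(self):
        rng = np.random.default_rng(3)
        data = np.hypot(rng.normal(0, 0.4787, (1, 64, 64)), rng.normal(0, 0.4787, (1, 64, 64)))
        stack = ImageStack(data, AcquisitionSchedule.blip(n_echoes=1))
        corrected = rician_bias_correct(stack, 0.4787)
        assert corrected.data.mean() < 0.6 * stack.data.mean()
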