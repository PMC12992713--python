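"""Generator contracts: linearity, Rician/Rayleigh noise, perturbations."""

import numpy as np
import pytest

from fluorad import synthdata as sd
from fluorad.volume import ScanVolume

RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # × sigma


def small_acq(**kw):
    return sd.AcquisitionSpec(shape=kw.pop("shape", (32, 32, 6)), **kw)


class TestRenderPhantom:
    def test_zero_concentration_tube_contributes_nothing(self):
        acq = small_acq()
        tube = sd.Tube(tuple(acq.extent / 2), 3.0, 6.0, 0.0)
        vol = sd.render_phantom(sd.PhantomSpec([tube]), acq)
        assert np.all(vol.data == 0)

    def test_intensity_linear_in_concentration(self):
        acq = small_acq()
        spec = sd.PhantomSpec(
            [sd.Tube(tuple(acq.extent / 2), 3.0, 6.0, sd.LOW_F19_MM)]
        )
        v1 = sd.render_phantom(spec, acq)
        v2 = sd.render_phantom(spec.scaled(2.0), acq)
        np.testing.assert_allclose(v2.data, 2.0 * v1.data, rtol=1e-12)

    def test_high_low_tube_ratio_matches_nuclei_content(self):
        # 244 mM vs 118 mM ¹⁹F at equal gain: ratio 244/118 ≈ 2.068
        acq = small_acq()
        center = tuple(acq.extent / 2)
        hi = sd.render_phantom(
            sd.PhantomSpec([sd.Tube(center, 3.0, 6.0, sd.HIGH_F19_MM)]), acq
        )
        lo = sd.render_phantom(
            sd.PhantomSpec([sd.Tube(center, 3.0, 6.0, sd.LOW_F19_MM)]), acq
        )
        assert hi.data.max() / lo.data.max() == pytest.approx(244.0 / 118.0, rel=1e-12)

    def test_tube_outside_grid_warns_and_contributes_nothing(self):
        acq = small_acq()
        far = sd.Tube((-100.0, -100.0, -100.0), 2.0, 5.0, 100.0)
        with pytest.warns(UserWarning, match="outside"):
            vol = sd.render_phantom(sd.PhantomSpec([far]), acq)
        assert np.all(vol.data == 0)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            sd.render_phantom(sd.PhantomSpec([]), small_acq(gain=-1.0))

    def test_partial_volume_fractions_at_boundary(self):
        acq = small_acq()
        vol = sd.render_phantom(
            sd.PhantomSpec([sd.Tube(tuple(acq.extent / 2), 3.0, 6.0, 100.0)]), acq
        )
        interior = acq.gain * 100.0
        frac = vol.data / interior
        assert ((frac > 0) & (frac < 1)).any()  # boundary voxels are fractional
        assert np.all((frac >= 0) & (frac <= 1 + 1e-12))


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        vol = ScanVolume(np.full((8, 8, 4), 5.0))
        out = sd.add_rician_noise(vol, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            sd.add_rician_noise(ScanVolume(np.zeros((4, 4, 2))), -0.1, seed=1)

    def test_background_follows_rayleigh_mean(self):
        # Rayleigh mean = sigma·sqrt(pi/2) ≈ 1.2533·sigma, Monte Carlo at 1e5
        sigma = 2.0
        vol = ScanVolume(np.zeros((50, 50, 40)))
        out = sd.add_rician_noise(vol, sigma, seed=5)
        assert out.data.mean() == pytest.approx(sigma * RAYLEIGH_MEAN, rel=0.01)

    def test_background_rayleigh_distribution(self):
        from scipy import stats

        sigma = 1.0
        out = sd.add_rician_noise(ScanVolume(np.zeros((50, 50, 40))), sigma, seed=9)
        d = stats.kstest(out.data.ravel(), stats.rayleigh(scale=sigma).cdf).statistic
        assert d < 0.01

    def test_same_seed_bit_identical(self):
        vol = ScanVolume(np.linspace(0, 10, 64).reshape(4, 4, 4))
        a = sd.add_rician_noise(vol, 1.0, seed=3)
        b = sd.add_rician_noise(vol, 1.0, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_output_nonnegative(self):
        vol = ScanVolume(np.zeros((16, 16, 4)))
        out = sd.add_rician_noise(vol, 3.0, seed=2)
        assert np.all(out.data >= 0)


class TestNoiseScan:
    def test_per_slice_mean_near_rayleigh(self):
        acq = sd.AcquisitionSpec(sigma=1.5)
        scan = sd.acquire_noise_scan(acq, seed=21)
        slice_means = scan.data.mean(axis=(0, 1))
        np.testing.assert_allclose(
            slice_means, 1.5 * RAYLEIGH_MEAN, rtol=0.05
        )

    def test_sigma_zero_all_zero(self):
        scan = sd.acquire_noise_scan(small_acq(sigma=0.0), seed=1)
        assert np.all(scan.data == 0)

    def test_different_seeds_differ(self):
        acq = small_acq()
        a = sd.acquire_noise_scan(acq, seed=1)
        b = sd.acquire_noise_scan(acq, seed=2)
        assert not np.array_equal(a.data, b.data)


class TestSessionPerturbation:
    def test_identity_perturbation_changes_nothing(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition()
        spec2, acq2 = sd.apply_session_perturbation(spec, acq, sd.SessionPerturbation())
        for a, b in zip(spec.tubes, spec2.tubes):
            np.testing.assert_allclose(a.center, b.center, atol=1e-12)
            np.testing.assert_allclose(a.axis, b.axis, atol=1e-12)
        assert acq2.gain == acq.gain and acq2.sigma == acq.sigma

    def test_translation_by_one_voxel_shifts_render(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition()
        pert = sd.SessionPerturbation(translation=(acq.spacing[0], 0, 0))
        spec2, acq2 = sd.apply_session_perturbation(spec, acq, pert)
        v1 = sd.render_phantom(spec, acq)
        v2 = sd.render_phantom(spec2, acq2)
        np.testing.assert_allclose(v2.data[1:, :, :], v1.data[:-1, :, :], atol=1e-9)

    def test_gain_factor_scales_noiseless_volume(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition()
        spec2, acq2 = sd.apply_session_perturbation(
            spec, acq, sd.SessionPerturbation(gain_factor=1.1)
        )
        v1 = sd.render_phantom(spec, acq)
        v2 = sd.render_phantom(spec2, acq2)
        np.testing.assert_allclose(v2.data, 1.1 * v1.data, rtol=1e-12)

    def test_moving_everything_out_of_grid_rejected(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition()
        with pytest.raises(ValueError, match="outside"):
            sd.apply_session_perturbation(
                spec, acq, sd.SessionPerturbation(translation=(500.0, 500.0, 500.0))
            )

    def test_bias_field_mean_one_amplitude_exact(self):
        acq = sd.AcquisitionSpec(bias_amplitude=0.1)
        b = sd.bias_field(acq)
        assert b.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(b - 1).max() == pytest.approx(0.1, rel=1e-9)


class TestTestRetest:
    def test_intrasession_zero_noise_bit_identical(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition(sigma=0.0)
        t, r = sd.simulate_test_retest(spec, acq, "intrasession", seeds=(1, 2))
        np.testing.assert_array_equal(t.data, r.data)

    def test_intrasession_difference_has_zero_median(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition()
        t, r = sd.simulate_test_retest(spec, acq, "intrasession", seeds=(1, 2))
        assert abs(np.median(t.data - r.data)) < 0.05

    def test_intrasession_rejects_perturbation(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition()
        with pytest.raises(ValueError, match="perturbation"):
            sd.simulate_test_retest(
                spec,
                acq,
                "intrasession",
                seeds=(1, 2),
                pert=sd.SessionPerturbation(gain_factor=1.1),
            )

    def test_intersession_requires_perturbation(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition()
        with pytest.raises(ValueError, match="requires"):
            sd.simulate_test_retest(spec, acq, "intersession", seeds=(1, 2))

    def test_arm_metadata(self):
        spec, acq = sd.default_phantom(), sd.default_acquisition()
        t, r = sd.simulate_test_retest(spec, acq, "intrasession", seeds=(1, 2))
        assert t.meta["arm"] == "test" and r.meta["arm"] == "retest"


class TestInvivoScene:
    def test_mask_has_three_labels(self):
        acq = sd.default_acquisition()
        (_, _), labels = sd.render_invivo_scene(acq, seeds=(1, 2), texture_seed=3)
        assert sorted(set(np.unique(labels)) - {0}) == [1, 2, 3]

    def test_reference_tube_intensity_proportional_to_gain(self):
        acq1 = sd.default_acquisition(sigma=0.0)
        acq2 = sd.default_acquisition(sigma=0.0, gain=2 * acq1.gain)
        (t1, _), lab = sd.render_invivo_scene(acq1, seeds=(1, 2), texture_seed=3)
        (t2, _), _ = sd.render_invivo_scene(acq2, seeds=(1, 2), texture_seed=3)
        m1 = t1.data[lab == 3].mean()
        m2 = t2.data[lab == 3].mean()
        assert m2 / m1 == pytest.approx(2.0, rel=1e-9)
        # and the tube interior sits at gain × reference concentration
        assert t1.data[lab == 3].max() == pytest.approx(
            acq1.gain * sd.REFERENCE_TUBE_F19_MM, rel=0.05
        )

    def test_same_seeds_identical_scene(self):
        acq = sd.default_acquisition()
        (a1, a2), la = sd.render_invivo_scene(acq, seeds=(4, 5), texture_seed=6)
        (b1, b2), lb = sd.render_invivo_scene(acq, seeds=(4, 5), texture_seed=6)
        np.testing.assert_array_equal(a1.data, b1.data)
        np.testing.assert_array_equal(a2.data, b2.data)
        np.testing.assert_array_equal(la, lb)


class TestDetectionSeries:
    def test_calibration_monotone_and_floor(self):
        acq = small_acq(shape=(32, 32, 8))
        out = sd.detection_series([0.0, 10.0, 50.0, 118.0, 244.0], acq, 3, 77)
        means = [r["mean_intensity"] for r in out["table"]]
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
        assert out["table"][0]["above_floor"] is False  # blank stays below 5×SD
        assert out["detection_floor_mm"] is not None

    def test_zero_concentration_sits_at_rayleigh_background(self):
        acq = small_acq(shape=(32, 32, 8))
        out = sd.detection_series([0.0, 244.0], acq, 4, 78)
        bg = out["table"][0]["mean_intensity"]
        assert bg == pytest.approx(acq.sigma * RAYLEIGH_MEAN, rel=0.05)

    def test_linear_above_floor_with_background_intercept(self):
        acq = small_acq(shape=(32, 32, 8))
        concs = [50.0, 100.0, 150.0, 200.0, 250.0]
        out = sd.detection_series(concs, acq, 3, 79)
        means = [r["mean_intensity"] for r in out["table"]]
        slope, intercept = np.polyfit(concs, means, 1)
        assert slope == pytest.approx(acq.gain, rel=0.05)
        assert abs(intercept) < 5 * acq.sigma

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(ValueError):
            sd.detection_series([], small_acq(), 3, 1)


def test_seed_expansion_deterministic_and_bounded():
    a = sd.spawn_seeds(123, 10)
    b = sd.spawn_seeds(123, 10)
    assert a == b and len(set(a)) == 10
    assert all(0 <= s < 2**31 for s in a)
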