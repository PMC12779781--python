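import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import marrowdose as md
from marrowdose.kinetics import TacFit
from marrowdose.volume_io import RegionMask, VoxelVolume

T4 = np.array([1.0, 36.0, 84.0, 132.0]) * 3600.0


class TestFitVoxelTac:
    @pytest.mark.parametrize("truth, make", [
        ("mono", lambda t: 100.0 * np.exp(-1e-4 * t)),
        ("biexp3", lambda t: 50.0 * (np.exp(-2e-6 * t) - np.exp(-3e-5 * t))),
    ])
    def test_noise_free_recovery(self, truth, make):
        fit = md.fit_voxel_tac(T4, make(T4))
        assert fit.model == truth
        if truth == "mono":
            a0, lam = fit.params
            assert a0 == pytest.approx(100.0, rel=1e-3)
            assert lam == pytest.approx(1e-4, rel=1e-3)
        else:
            a, l1, l2 = fit.params
            assert a == pytest.approx(50.0, rel=1e-3)
            assert l1 == pytest.approx(2e-6, rel=1e-3)
            assert l2 == pytest.approx(3e-5, rel=1e-3)
            assert l2 > l1

    def test_all_zero_degenerate(self):
        fit = md.fit_voxel_tac(T4, np.zeros(4))
        assert fit.degenerate
        assert md.integrate_tac(fit) == 0.0

    def test_three_timepoints_mono_only(self):
        t = T4[:3]
        a = 50.0 * (np.exp(-2e-6 * t) - np.exp(-3e-5 * t))
        fit = md.fit_voxel_tac(t, a)
        assert fit.model == "mono"  # biexp3 ineligible at n = 3

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            md.fit_voxel_tac(T4[:2], [1.0, 2.0])
        with pytest.raises(ValueError):
            md.fit_voxel_tac([1.0, 1.0, 2.0], [1.0, 2.0, 3.0])


class TestIntegrateTac:
    def test_mono_closed_form(self):
        fit = TacFit("mono", (100.0, 1e-4), 0.0, 0.0)
        assert md.integrate_tac(fit) == pytest.approx(1.0e6)

    def test_biexp_closed_form(self):
        fit = TacFit("biexp3", (50.0, 1e-4, 1e-3), 0.0, 0.0)
        assert md.integrate_tac(fit) == pytest.approx(4.5e5)

    def test_degenerate_equal_rates(self):
        fit = TacFit("biexp3", (50.0, 1e-4, 1e-4), 0.0, 0.0)
        assert md.integrate_tac(fit) == 0.0

    def test_nonpositive_rate_errors(self):
        with pytest.raises(ValueError):
            md.integrate_tac(TacFit("mono", (10.0, 0.0), 0.0, 0.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_linearity_in_amplitude(self, c):
        base = md.integrate_tac(TacFit("mono", (10.0, 2e-5), 0.0, 0.0))
        scaled = md.integrate_tac(TacFit("mono", (10.0 * c, 2e-5), 0.0, 0.0))
        assert scaled == pytest.approx(c * base, rel=1e-12)


class TestModelSelectionConsistency:
    def test_noise_free_always_correct(self):
        for i in range(40):
            if i % 2:
                truth, a = "mono", 40.0 * np.exp(-(3e-6 + i * 1e-7) * T4)
            else:
                truth, a = "biexp3", 60.0 * (np.exp(-2e-6 * T4)
                                             - np.exp(-3e-5 * T4))
            assert md.fit_voxel_tac(T4, a).model == truth

    def test_noisy_selection_rate(self):
        # 500 seeded voxels, 5% CV, five-sample schedule
        t = np.array([1.0, 24.0, 48.0, 96.0, 144.0]) * 3600.0
        rng = np.random.default_rng(42)
        correct = 0
        for i in range(500):
            if i % 2 == 0:
                truth, a = "mono", 40.0 * np.exp(-5e-6 * t)
            else:
                truth, a = "biexp3", 60.0 * (np.exp(-2e-6 * t)
                                             - np.exp(-3e-5 * t))
            noisy = np.maximum(a * (1 + 0.05 * rng.standard_normal(t.size)), 0)
            correct += md.fit_voxel_tac(t, noisy).model == truth
        assert correct / 500 >= 0.90


class TestBuildTiaMap:
    def test_phantom_truth_recovered(self, phantom_bundle):
        series = md.simulate_timepoint_images(phantom_bundle, [1, 36, 84, 132])
        mask = phantom_bundle.masks["sacrum"]
        tia = md.build_tia_map(series, T4, mask)
        sel = mask.as_bool()
        truth = phantom_bundle.true_tia.data[sel]
        np.testing.assert_allclose(tia.tia.data[sel], truth, rtol=5e-3)
        assert np.all(tia.tia.data[~sel] == 0)
        assert tia.tia.unit == "MBq·s"

    def test_extra_consistent_timepoint_changes_nothing(self, phantom_bundle):
        mask = phantom_bundle.masks["femur_left"]
        s4 = md.simulate_timepoint_images(phantom_bundle, [1, 36, 84, 132])
        s5 = md.simulate_timepoint_images(phantom_bundle, [1, 36, 84, 132, 168])
        t5 = np.array([1, 36, 84, 132, 168.0]) * 3600.0
        tia4 = md.build_tia_map(s4, T4, mask)
        tia5 = md.build_tia_map(s5, t5, mask)
        sel = mask.as_bool()
        np.testing.assert_allclose(tia5.tia.data[sel], tia4.tia.data[sel],
                                   rtol=1e-3)

    def test_empty_mask_all_zero(self, phantom_bundle):
        series = md.simulate_timepoint_images(phantom_bundle, [1, 36, 84])
        empty = RegionMask(np.zeros(phantom_bundle.ct_hu.shape, np.uint8),
                           "empty", phantom_bundle.ct_hu.spacing)
        tia = md.build_tia_map(series, T4[:3], empty)
        assert tia.tia.data.sum() == 0

    def test_grid_mismatch_errors(self, phantom_bundle):
        series = md.simulate_timepoint_images(phantom_bundle, [1, 36, 84])
        series[1] = VoxelVolume(series[1].data, (1, 1, 1), "kBq/mL")
        with pytest.raises(Exception, match="grid"):
            md.build_tia_map(series, T4[:3],
                             phantom_bundle.masks["sacrum"])


class TestBloodCurve:
    def test_known_integral_recovered(self):
        t = np.array([0.5, 4, 24, 48, 96, 144.0]) * 3600.0
        c = 10.0 * np.exp(-1e-3 * t) + 2.0 * np.exp(-1e-5 * t)
        fit = md.fit_blood_curve(t, c)
        assert fit.integral == pytest.approx(10 / 1e-3 + 2 / 1e-5, rel=1e-3)

    def test_single_exponential_limit(self):
        t = np.array([1, 24, 48, 96, 144.0]) * 3600.0
        c = 8.0 * np.exp(-2e-5 * t)
        fit = md.fit_blood_curve(t, c)
        assert fit.integral == pytest.approx(8.0 / 2e-5, rel=1e-2)

    def test_too_few_samples_instructs_fallback(self):
        with pytest.raises(ValueError, match="mono fallback"):
            md.fit_blood_curve([0, 3600, 7200], [3, 2, 1])

    def test_non_increasing_times_error(self):
        with pytest.raises(ValueError, match="increasing"):
            md.fit_blood_curve([0, 7200, 3600, 9000], [3, 2, 1, 1])
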