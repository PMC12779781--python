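import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import marrowdose as md
from marrowdose.marrow_model import (DensityCalibration, make_reference_region,
                                     sc_mass_map)
from marrowdose.volume_io import RegionMask, VoxelVolume


class TestCalibration:
    def test_water_anchor(self):
        calib = DensityCalibration()
        assert calib.density(0.0) == pytest.approx(1.0)

    def test_continuity_at_breakpoint(self):
        calib = DensityCalibration()
        lo = calib.soft_intercept + calib.soft_slope * calib.breakpoint_hu
        hi = calib._rho_break + calib.bone_slope * 0.0
        assert lo == pytest.approx(hi)
        eps = 1e-9
        assert calib.density(calib.breakpoint_hu - eps) == pytest.approx(
            calib.density(calib.breakpoint_hu + eps), abs=1e-8)

    def test_round_trip_through_inverse(self):
        calib = DensityCalibration()
        rho = np.linspace(0.95, 1.6, 50)
        np.testing.assert_allclose(calib.density(calib.hu(rho)), rho,
                                   atol=1e-9)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            DensityCalibration(bone_slope=-0.1)

    def test_hu_unit_required(self):
        vol = VoxelVolume(np.zeros((2, 2, 2)), (1, 1, 1), "g/mL")
        with pytest.raises(ValueError, match="HU"):
            md.hu_to_density(vol)


class TestCompartmentArithmetic:
    def test_marrow_density_values(self):
        assert md.marrow_density(0.40) == pytest.approx(1.000)
        assert md.marrow_density(1.0) == pytest.approx(1.03)
        assert md.marrow_density(0.0) == pytest.approx(0.98)
        with pytest.raises(ValueError):
            md.marrow_density(1.2)

    def test_bvf_from_density_fig_pair(self):
        bvf, clamped = md.bvf_from_density(1.1564, 0.40)
        assert bvf == pytest.approx(0.17)
        assert not clamped

    def test_marrow_only_voxel_zero_bvf(self):
        bvf, _ = md.bvf_from_density(md.marrow_density(0.6), 0.6)
        assert bvf == pytest.approx(0.0, abs=1e-14)

    def test_pure_bone_clamped_and_flagged(self):
        bvf, clamped = md.bvf_from_density(1.92, 0.40)
        assert bvf == 0.98
        assert clamped

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.97), st.floats(0.01, 0.99))
    def test_forward_inverse_identity(self, bvf, cf):
        rho = md.compose_voxel_density(bvf, cf)
        back, clamped = md.bvf_from_density(rho, cf)
        assert abs(back - bvf) <= 1e-12


class TestReferenceMass:
    def test_printed_example(self):
        assert md.reference_rm_mass(0.17, 0.40, 100.0) == pytest.approx(34.196)

    def test_zero_cf_zero_mass_and_linearity(self):
        assert md.reference_rm_mass(0.2, 0.0, 50.0) == 0.0
        one = md.reference_rm_mass(0.2, 0.5, 50.0)
        assert md.reference_rm_mass(0.2, 0.5, 100.0) == pytest.approx(2 * one)

    def test_nonpositive_volume_errors(self):
        with pytest.raises(ValueError):
            md.reference_rm_mass(0.2, 0.5, 0.0)


class TestScMassMap:
    def _setup(self, sc_value=7.8):
        shape = (6, 6, 6)
        sp = (4.0, 4.0, 4.0)
        mask = RegionMask(np.ones(shape, np.uint8), "site", sp)
        sc = VoxelVolume(np.full(shape, sc_value), sp, "kBq/mL")
        density = VoxelVolume(np.full(shape, md.compose_voxel_density(0.17, 0.40)),
                              sp, "g/mL")
        ref = make_reference_region(mask, density, sc, cf_ref=0.40)
        return mask, sc, ref

    def test_uniform_reference_conserves_mass(self):
        mask, sc, ref = self._setup()
        assert ref.sc_conc_ref == pytest.approx(7.8)
        mass = sc_mass_map(sc, ref, {"site": mask})
        total = mass.data[mask.as_bool()].sum()
        assert total == pytest.approx(ref.m_rm_ref_g, rel=1e-12)

    def test_linear_in_sc_intensity(self):
        mask, sc, ref = self._setup()
        m1 = sc_mass_map(sc, ref, {"site": mask})
        m2 = sc_mass_map(sc.with_data(2.0 * np.asarray(sc.data)), ref,
                         {"site": mask})
        np.testing.assert_allclose(m2.data, 2.0 * m1.data)

    def test_zero_sc_zero_mass(self):
        mask, sc, ref = self._setup()
        dark = sc.with_data(np.zeros_like(np.asarray(sc.data)))
        assert sc_mass_map(dark, ref, {"site": mask}).data.sum() == 0.0

    def test_zero_reference_conc_errors(self):
        mask, sc, ref = self._setup()
        ref.sc_conc_ref = 0.0
        with pytest.raises(ValueError):
            sc_mass_map(sc, ref, {"site": mask})


class TestInvertCfBvf:
    def test_worked_pair(self):
        bvf, cf, clamped = md.invert_cf_bvf(1.184, 0.3296, 1.0)
        assert bvf == pytest.approx(0.20, abs=1e-12)
        assert cf == pytest.approx(0.40, abs=1e-12)
        assert not clamped

    def test_brute_force_grid_agrees(self):
        # independent oracle: nearest grid point over (bvf, cf)
        rho_t, m_t = 1.184, 0.3296
        grid_b = np.linspace(0, 0.5, 501)
        grid_c = np.linspace(0, 1, 501)
        bb, cc = np.meshgrid(grid_b, grid_c, indexing="ij")
        rho = md.compose_voxel_density(bb, cc)
        mass = (1 - bb) * cc * 1.0 * 1.03
        err = (rho - rho_t) ** 2 / rho_t ** 2 + (mass - m_t) ** 2 / m_t ** 2
        i, j = np.unravel_index(np.argmin(err), err.shape)
        assert grid_b[i] == pytest.approx(0.20, abs=2e-3)
        assert grid_c[j] == pytest.approx(0.40, abs=2e-3)

    def test_zero_mass_reduces_to_cf0(self):
        rho = md.compose_voxel_density(0.3, 0.0)
        bvf, cf, _ = md.invert_cf_bvf(rho, 0.0, 1.0)
        assert cf == 0.0
        assert bvf == pytest.approx(0.3, abs=1e-12)

    def test_overfull_voxel_clamped_flagged(self):
        _, _, clamped = md.invert_cf_bvf(1.03, 2.0, 1.0)
        assert clamped

    def test_round_trip_1000_random_pairs(self):
        rng = np.random.default_rng(8)
        bvf = rng.uniform(0.0, 0.9, 1000)
        cf = rng.uniform(0.01, 0.99, 1000)
        v = 0.064
        rho = md.compose_voxel_density(bvf, cf)
        mass = (1 - bvf) * cf * v * 1.03
        b2, c2, clamped = md.invert_cf_bvf(rho, mass, v)
        assert np.abs(b2 - bvf).max() <= 1e-10
        assert np.abs(c2 - cf).max() <= 1e-10
        assert not clamped.any()


class TestTumorMask:
    def _suv(self, values):
        return VoxelVolume(values, (4, 4, 4), "SUV")

    def test_strict_threshold_boundary(self):
        vals = np.full((3, 3, 3), 1.0)
        vals[0, 0, 0] = 3.0   # exactly at threshold: excluded
        vals[1, 1, 1] = 3.01
        skel = RegionMask(np.ones((3, 3, 3), np.uint8), "s", (4, 4, 4))
        tumor = md.tumor_mask_from_pet(self._suv(vals), {"s": skel})
        assert tumor.n_voxels == 1
        assert tumor.data[1, 1, 1] == 1

    def test_threshold_above_max_empty(self):
        skel = RegionMask(np.ones((3, 3, 3), np.uint8), "s", (4, 4, 4))
        tumor = md.tumor_mask_from_pet(self._suv(np.full((3, 3, 3), 2.0)),
                                       {"s": skel}, threshold=3.0)
        assert tumor.n_voxels == 0

    def test_outside_skeleton_ignored(self):
        vals = np.full((3, 3, 3), 5.0)
        skel = np.zeros((3, 3, 3), np.uint8)
        skel[0] = 1
        tumor = md.tumor_mask_from_pet(
            self._suv(vals), {"s": RegionMask(skel, "s", (4, 4, 4))})
        assert tumor.n_voxels == 9


def test_packaged_materials_config_matches_code_defaults():
    cfg = md.load_materials_config()
    assert cfg["materials"] == md.MaterialConstants()
    assert cfg["calibration"].density(0.0) == pytest.approx(1.0)
    assert cfg["site_cf"]["lumbar_spine"] == pytest.approx(0.70)
    assert md.age_based_cf(20.0, cfg["age_cf"]) == pytest.approx(0.70)


def test_age_based_cf_interpolates():
    assert md.age_based_cf(20.0) == pytest.approx(0.70)
    assert md.age_based_cf(50.0) == pytest.approx(0.55)
    assert md.age_based_cf(120.0) == pytest.approx(0.40)
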