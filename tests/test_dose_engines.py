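import numpy as np
import pytest

import marrowdose as md
from marrowdose.dose_engines import PatientHematology, pve_correct_tia
from marrowdose.kinetics import TiaMap
from marrowdose.physics import MEV_TO_J
from marrowdose.volume_io import RegionMask, VoxelVolume


class TestMirdClosedForm:
    def test_worked_example(self):
        # A=3.6e6 MBq·s, v=2250 mL -> m_RM = 1205.1 g = phantom mass,
        # D = 3.6e6 * 1.07e-5 mGy = 0.03852 Gy
        assert md.dose_mird(3.6e6, 2250.0) == pytest.approx(0.03852, rel=1e-12)

    def test_zero_tia_zero_dose(self):
        assert md.dose_mird(0.0, 1000.0) == 0.0

    def test_mass_scaling_inverse_in_volume(self):
        d1 = md.dose_mird(1e6, 2000.0)
        d2 = md.dose_mird(1e6, 1000.0)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_independent_hand_computation_100_random(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            tia = float(rng.uniform(1e4, 1e7))
            v = float(rng.uniform(500, 4000))
            # independent evaluation written out from first principles
            m_rm = 1.03 * v * 0.52
            hand = tia * 1.07e-5 * (1.03 * 1170.0 / m_rm) * 1e-3
            assert md.dose_mird(tia, v) == pytest.approx(hand, rel=1e-12)


class TestMirdAorta:
    def test_worked_example(self):
        hem = PatientHematology(0.45)
        d = md.dose_mird_aorta(100.0, hem, 1205.1)
        hand = 100.0 * (0.19 / 0.55) * 1205.1 * 1.07e-5 * 1e-3
        assert d == pytest.approx(hand, rel=1e-12)
        assert d == pytest.approx(0.4454e-3, rel=1e-3)

    def test_hct_zero_limit(self):
        assert PatientHematology(0.0).rmblr == pytest.approx(0.19)

    def test_fixed_rmblr_one_scaling(self):
        base = md.dose_mird_aorta(50.0, PatientHematology(0.45), 800.0)
        unity = md.dose_mird_aorta(50.0, PatientHematology(0.45,
                                                           fixed_rmblr=1.0),
                                   800.0)
        assert unity / base == pytest.approx(1.0 / (0.19 / 0.55), rel=1e-12)

    def test_hand_computation_100_random(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            tia_c = float(rng.uniform(1, 1e4))
            hct = float(rng.uniform(0.2, 0.6))
            m = float(rng.uniform(300, 2000))
            hand = tia_c * 0.19 / (1 - hct) * m * 1.07e-5 * 1e-3
            got = md.dose_mird_aorta(tia_c, PatientHematology(hct), m)
            assert got == pytest.approx(hand, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PatientHematology(1.2)
        with pytest.raises(ValueError):
            md.dose_mird_aorta(1.0, PatientHematology(0.4), 0.0)


def _uniform_phantom(shape=(7, 7, 7), sp=12.0, tia_per_voxel=2.0):
    spacing = (sp, sp, sp)
    tia = TiaMap(VoxelVolume(np.full(shape, tia_per_voxel), spacing, "MBq·s"),
                 np.zeros(shape, np.int8))
    density = VoxelVolume(np.full(shape, 1.0), spacing, "g/mL")
    return tia, density


class TestMacroMc:
    def test_equilibrium_dose_oracle(self, tiny_eaf3, decay_data):
        # uniform TIA in uniform soft tissue: central voxel dose equals
        # [A_tilde] * mean electron energy / rho
        tia, density = _uniform_phantom()
        dose, rep = md.run_macro_mc(tia, density, {}, {}, tiny_eaf3,
                                    decay_data, n_histories=400_000, seed=5)
        conc = 2.0 / density.voxel_volume_ml  # MBq·s per mL
        expected = conc * 1e6 * decay_data.mean_electron_energy_mev \
            * MEV_TO_J / 1e-3
        assert dose.data[3, 3, 3] == pytest.approx(expected, rel=0.04)

    def test_linearity_in_tia(self, tiny_eaf3, decay_data):
        tia, density = _uniform_phantom(shape=(5, 5, 5))
        d1, _ = md.run_macro_mc(tia, density, {}, {}, tiny_eaf3, decay_data,
                                n_histories=20_000, seed=9)
        tia2 = TiaMap(tia.tia.with_data(2.0 * np.asarray(tia.tia.data)),
                      tia.model_choice)
        d2, _ = md.run_macro_mc(tia2, density, {}, {}, tiny_eaf3, decay_data,
                                n_histories=20_000, seed=9)
        np.testing.assert_allclose(d2.data, 2.0 * d1.data, rtol=1e-9)

    def test_zero_tia_zero_dose(self, tiny_eaf3, decay_data):
        tia, density = _uniform_phantom(tia_per_voxel=0.0)
        dose, rep = md.run_macro_mc(tia, density, {}, {}, tiny_eaf3,
                                    decay_data, n_histories=1000, seed=1)
        assert dose.data.sum() == 0.0

    def test_energy_bookkeeping_exact(self, tiny_eaf3, decay_data,
                                      phantom_bundle, phantom_density):
        tia = TiaMap(phantom_bundle.true_tia,
                     np.zeros(phantom_bundle.ct_hu.shape, np.int8))
        site = {"sacrum": phantom_bundle.masks["sacrum"]}
        _, rep = md.run_macro_mc(tia, phantom_density, site,
                                 {"sacrum": 0.70}, tiny_eaf3, decay_data,
                                 n_histories=50_000, seed=3)
        d = rep.diagnostics
        residual = (d["energy_emitted_mev"] - d["energy_deposited_mev"]
                    - d["energy_escaped_mev"])
        assert abs(residual) <= 1e-9 * d["energy_emitted_mev"]

    def test_missing_site_cf_errors(self, tiny_eaf3, decay_data,
                                    phantom_bundle, phantom_density):
        tia = TiaMap(phantom_bundle.true_tia,
                     np.zeros(phantom_bundle.ct_hu.shape, np.int8))
        with pytest.raises(KeyError, match="sacrum"):
            md.run_macro_mc(tia, phantom_density,
                            {"sacrum": phantom_bundle.masks["sacrum"]}, {},
                            tiny_eaf3, decay_data, n_histories=1000, seed=1)

    def test_seeded_determinism(self, tiny_eaf3, decay_data):
        tia, density = _uniform_phantom(shape=(5, 5, 5))
        d1, _ = md.run_macro_mc(tia, density, {}, {}, tiny_eaf3, decay_data,
                                n_histories=10_000, seed=77)
        d2, _ = md.run_macro_mc(tia, density, {}, {}, tiny_eaf3, decay_data,
                                n_histories=10_000, seed=77)
        np.testing.assert_array_equal(d1.data, d2.data)


class TestPveCorrection:
    def _region(self, marrow_tia=(60.0, 60.0), tumor_tia=(10.0, 30.0),
                with_tumor=True):
        shape = (4, 1, 1)
        sp = (10.0, 10.0, 10.0)
        tia = np.zeros(shape)
        tia[0, 0, 0], tia[1, 0, 0] = marrow_tia
        mask = np.ones(shape, np.uint8)
        tumor = np.zeros(shape, np.uint8)
        if with_tumor:
            tia[2, 0, 0], tia[3, 0, 0] = tumor_tia
            tumor[2, 0, 0] = tumor[3, 0, 0] = 1
        rm_mass = np.zeros(shape)
        rm_mass[0, 0, 0] = rm_mass[1, 0, 0] = 0.5  # g
        tmap = TiaMap(VoxelVolume(tia, sp, "MBq·s"), np.zeros(shape, np.int8))
        return (tmap, VoxelVolume(rm_mass, sp, "g"),
                {"region": RegionMask(mask, "region", sp)},
                RegionMask(tumor, "tumor", sp))

    def test_spill_out_conserves_region_total(self):
        tmap, rm, regions, tumor = self._region()
        # imaged marrow 120, expected 100 * 1.0 g = 100 -> excess 20 to tumor
        out = pve_correct_tia(tmap, rm, 100.0, regions, tumor)
        marrow = out.tia.data[:2].sum()
        assert marrow == pytest.approx(100.0, rel=1e-12)
        assert out.tia.data.sum() == pytest.approx(tmap.tia.data.sum(),
                                                   rel=1e-12)
        # excess distributed proportional to existing tumor TIA (10:30)
        assert out.tia.data[2, 0, 0] == pytest.approx(10 + 20 * 0.25)
        assert out.tia.data[3, 0, 0] == pytest.approx(30 + 20 * 0.75)

    def test_spill_in_raises_marrow_to_blood_value(self):
        tmap, rm, regions, tumor = self._region(marrow_tia=(40.0, 40.0))
        out = pve_correct_tia(tmap, rm, 100.0, regions, tumor)
        assert out.tia.data[:2].sum() == pytest.approx(100.0, rel=1e-12)
        added = out.tia.data.sum() - tmap.tia.data.sum()
        assert added == pytest.approx(100.0 - 80.0, rel=1e-12)

    def test_fixed_point_when_equal(self):
        tmap, rm, regions, tumor = self._region(marrow_tia=(50.0, 50.0))
        out = pve_correct_tia(tmap, rm, 100.0, regions, tumor)
        np.testing.assert_allclose(out.tia.data, tmap.tia.data, atol=1e-12)

    def test_tumor_free_excess_discarded_with_warning(self, caplog):
        tmap, rm, regions, tumor = self._region(with_tumor=False)
        with caplog.at_level("WARNING"):
            out = pve_correct_tia(tmap, rm, 100.0, regions, tumor)
        assert out.tia.data.sum() == pytest.approx(100.0)
        assert any("discarded" in r.message for r in caplog.records)


class TestMcScPet:
    def test_requires_four_compartment_table(self, tiny_eaf3, decay_data,
                                             phantom_bundle, phantom_density):
        tia = TiaMap(phantom_bundle.true_tia,
                     np.zeros(phantom_bundle.ct_hu.shape, np.int8))
        rm = VoxelVolume(phantom_bundle.truth.rm_mass_g,
                         phantom_bundle.ct_hu.spacing, "g")
        tumor = RegionMask(np.zeros(phantom_bundle.ct_hu.shape, np.uint8),
                           "tumor", phantom_bundle.ct_hu.spacing)
        with pytest.raises(ValueError, match="4-compartment"):
            md.run_mc_sc_pet(tia, phantom_density, rm, tumor,
                             phantom_bundle.site_masks, tiny_eaf3, tiny_eaf3,
                             decay_data, n_histories=1000, seed=1)

    def test_zero_tia_zero_dose(self, tiny_eaf3, tiny_eaf4, decay_data,
                                phantom_bundle, phantom_density):
        shape = phantom_bundle.ct_hu.shape
        tia = TiaMap(phantom_bundle.true_tia.with_data(np.zeros(shape)),
                     np.zeros(shape, np.int8))
        rm = VoxelVolume(phantom_bundle.truth.rm_mass_g,
                         phantom_bundle.ct_hu.spacing, "g")
        tumor = RegionMask(np.zeros(shape, np.uint8), "tumor",
                           phantom_bundle.ct_hu.spacing)
        dose, rep = md.run_mc_sc_pet(tia, phantom_density, rm, tumor,
                                     phantom_bundle.site_masks, tiny_eaf3,
                                     tiny_eaf4, decay_data,
                                     n_histories=1000, seed=1)
        assert dose.data.sum() == 0.0
        assert rep.fov.dose_gy == 0.0
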