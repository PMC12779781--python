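"""The four red-marrow absorbed-dose calculations.

* ``dose_mird`` — total spongiosa TIA x skeletal-average self-dose S-value
  with a phantom/patient RM mass scaling:
  D = A_tilde * S_RM<-RM * m_RM,phantom / m_RM.
* ``dose_mird_aorta`` — blood-surrogate dosimetry: the aorta TIA
  concentration is mapped to marrow by the hematocrit-based red-marrow-to-
  blood ratio RMBLR = 0.19/(1-HCT) and multiplied by the patient RM mass and
  the same S-value (no phantom mass ratio; a mass-scaled variant is
  available behind a flag for sensitivity analysis).
* ``run_macro_mc`` — voxel Monte Carlo over the CT density map with
  micro-scale EAF apportioning in spongiosa voxels (3-compartment model,
  activity assumed to originate in RM).
* ``run_mc_sc_pet`` — as above but with sulfur-colloid-derived per-voxel
  (BVF, CF) and 4-compartment EAFs (equal tumor and marrow volume share)
  in PET-identified tumor voxels, where activity originates in tumor.
* ``pve_correct_tia`` — region-level partial-volume correction of the TIA
  map against the blood-derived expectation before MC_SC+PET.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import DecayData
from .eaf import EafTable
from .kinetics import TiaMap
from .marrow_model import (MATERIALS, CompartmentMaps, MaterialConstants,
                           compartment_maps_from_sc,
                           compartment_maps_from_sites)
from .physics import MEV_TO_J, PHOTON_WATER
from .transport import macro_transport, photon_kernel
from .volume_io import RegionMask, VoxelVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferencePhantomConstants:
    """Reference-man skeletal constants for the MIRD-schema engines."""

    s_rm_rm: float = 1.07e-5     # mGy / (MBq·s), RM <- RM self-dose S-value
    v_rm_phantom_ml: float = 1170.0
    f_rm: float = 0.52           # skeletal average RM volume fraction
    rho_rm: float = 1.03         # g/mL

    @property
    def m_rm_phantom_g(self) -> float:
        return self.rho_rm * self.v_rm_phantom_ml


REFERENCE_PHANTOM = ReferencePhantomConstants()


@dataclass
class PatientHematology:
    """Baseline hematocrit and the derived RM-to-blood concentration ratio."""

    hct: float
    fixed_rmblr: float | None = None  # set 1.0 for the RMBLR=1 convention

    def __post_init__(self):
        if not (0.0 <= self.hct < 1.0):
            raise ValueError("HCT must lie in [0, 1)")

    @property
    def rmblr(self) -> float:
        if self.fixed_rmblr is not None:
            return self.fixed_rmblr
        return 0.19 / (1.0 - self.hct)


@dataclass
class RegionDose:
    region: str
    rm_mass_g: float
    dose_gy: float
    se_gy: float = 0.0
    gy_per_gbq: float | None = None


@dataclass
class DoseReport:
    """Per-region and field-of-view RM absorbed dose for one method."""

    method: str
    regions: list = field(default_factory=list)
    fov: RegionDose | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [vars(r) for r in self.regions]
        if self.fov is not None:
            rows.append(vars(self.fov))
        df = pd.DataFrame(rows)
        df.insert(0, "method", self.method)
        return df


# ---------------------------------------------------------------------------
# Closed-form MIRD engines
# ---------------------------------------------------------------------------

def dose_mird(tia_total_spongiosa_mbqs: float, v_rm_segmented_ml: float,
              consts: ReferencePhantomConstants = REFERENCE_PHANTOM) -> float:
    """MIRD-schema RM dose (Gy) from the total spongiosa TIA.

    m_RM = rho_RM * v_RM_segmented * f_RM;
    D = A_tilde * S * (m_RM,phantom / m_RM).
    """
    if v_rm_segmented_ml <= 0:
        raise ValueError("segmented RM volume must be > 0")
    if tia_total_spongiosa_mbqs < 0:
        raise ValueError("TIA must be >= 0")
    m_rm = consts.rho_rm * v_rm_segmented_ml * consts.f_rm
    d_mgy = tia_total_spongiosa_mbqs * consts.s_rm_rm \
        * (consts.m_rm_phantom_g / m_rm)
    return d_mgy * 1e-3


def dose_mird_aorta(tia_conc_aorta_mbqs_per_g: float, hem: PatientHematology,
                    m_rm_g: float,
                    consts: ReferencePhantomConstants = REFERENCE_PHANTOM,
                    mass_scaled: bool = False) -> float:
    """Aorta-blood-surrogate RM dose (Gy).

    [A_tilde]_RM = [A_tilde]_aorta * RMBLR; D = [A_tilde]_RM * m_RM * S
    (exactly as printed; ``mass_scaled=True`` additionally applies the
    phantom/patient mass ratio for sensitivity analysis).
    """
    if m_rm_g <= 0:
        raise ValueError("RM mass must be > 0")
    tia_rm = tia_conc_aorta_mbqs_per_g * hem.rmblr
    d_mgy = tia_rm * m_rm_g * consts.s_rm_rm
    if mass_scaled:
        d_mgy *= consts.m_rm_phantom_g / m_rm_g
    return d_mgy * 1e-3


# ---------------------------------------------------------------------------
# Macro Monte Carlo engines
# ---------------------------------------------------------------------------

def _prepare_tia_cdf(tia: TiaMap) -> tuple[np.ndarray, float]:
    t = np.asarray(tia.tia.data, float).ravel()
    total = float(t.sum())
    if total <= 0:
        return np.array([]), 0.0
    cdf = np.cumsum(t) / total
    cdf[-1] = 1.0
    return cdf, total


def _dummy_table():
    return (np.zeros((1, 1, 1, 3, 5)), np.zeros(1), np.zeros(1), np.zeros(1))


def _table_arrays(table: EafTable):
    return (table.kernel_values(), np.ascontiguousarray(table.log_energies),
            np.ascontiguousarray(table.bvfs), np.ascontiguousarray(table.cfs))


def _region_rm_mass(maps: CompartmentMaps) -> np.ndarray:
    n = len(maps.region_names)
    out = np.zeros(n)
    for r in range(n):
        out[r] = maps.rm_mass_g[maps.region_id == r].sum()
    return out


def _run_mc(tia: TiaMap, density: VoxelVolume, maps: CompartmentMaps,
            tumor4: np.ndarray, eaf3: EafTable, eaf4: EafTable | None,
            decay: DecayData, n_histories: int, seed: int, method: str,
            photons: bool, n_batch: int,
            administered_gbq: float | None) -> tuple[VoxelVolume, DoseReport]:
    tia.tia.require_same_grid(density)
    cdf, tia_total = _prepare_tia_cdf(tia)
    shape = density.shape
    sx, sy, sz = density.spacing
    n_regions = max(len(maps.region_names), 1)
    region = np.ascontiguousarray(maps.region_id.astype(np.int16))
    rm_mass_region = _region_rm_mass(maps)
    report = DoseReport(method=method)
    v_vox_ml = density.voxel_volume_ml
    mass_kg = np.maximum(np.asarray(density.data, float), 1e-3) * v_vox_ml * 1e-3

    if tia_total <= 0:
        dose = density.with_data(np.zeros(shape), unit="Gy")
        for r, name in enumerate(maps.region_names):
            report.regions.append(RegionDose(name, rm_mass_region[r], 0.0))
        report.fov = RegionDose("FOV", rm_mass_region.sum(), 0.0)
        report.diagnostics = {"n_histories": 0, "seed": seed,
                              "tia_total_mbqs": 0.0}
        return dose, report

    v3, le3, ba3, ca3 = _table_arrays(eaf3)
    if eaf4 is not None:
        v4, le4, ba4, ca4 = _table_arrays(eaf4)
        has4 = 1
    else:
        v4, le4, ba4, ca4 = _dummy_table()
        has4 = 0

    edep, rm_batch, book = macro_transport(
        np.ascontiguousarray(np.asarray(density.data, float)),
        np.ascontiguousarray(maps.spongiosa.astype(np.uint8)),
        np.ascontiguousarray(np.asarray(tumor4, np.uint8)),
        region,
        np.ascontiguousarray(maps.bvf.astype(np.float64)),
        np.ascontiguousarray(maps.cf.astype(np.float64)),
        cdf, decay.beta_cdf, decay.beta_energy_mev,
        v3, le3, ba3, ca3, v4, le4, ba4, ca4, has4,
        sx, sy, sz, int(n_histories), int(n_batch),
        int(seed) % (2 ** 31 - 1), n_regions)

    mean_e = decay.mean_electron_energy_mev
    if photons and decay.photons:
        line_e = np.array([e for e, _ in decay.photons])
        line_y = np.array([y for _, y in decay.photons])
        mu = np.array([PHOTON_WATER[round(e, 4)][0] for e in line_e])
        muen = np.array([PHOTON_WATER[round(e, 4)][1] for e in line_e])
        with np.errstate(divide="ignore", invalid="ignore"):
            rmfrac = np.where(
                maps.spongiosa,
                maps.rm_mass_g / np.maximum(mass_kg * 1e3, 1e-12), 0.0)
        edep_p, rm_p, book_p = photon_kernel(
            np.ascontiguousarray(np.asarray(density.data, float)), region,
            np.ascontiguousarray(rmfrac), cdf, line_e, line_y, mu, muen,
            sx, sy, sz, int(n_histories), int(n_batch),
            (int(seed) + 7919) % (2 ** 31 - 1), n_regions)
        edep = edep + edep_p
        rm_batch = rm_batch + rm_p
        book = book + book_p
        mean_e = mean_e + decay.mean_photon_energy_mev

    # decays simulated vs decays represented: each history carries the mean
    # emission energy, so scale tallies by (total decays / n_histories)
    n_decays = tia_total * 1e6  # MBq·s -> decays
    scale = n_decays / n_histories
    dose_gy = edep * scale * MEV_TO_J / mass_kg
    dose = density.with_data(dose_gy, unit="Gy")

    def _dose_and_se(energy_batches_mev, mass_g):
        if mass_g <= 0:
            return 0.0, 0.0
        per_batch = energy_batches_mev * n_batch * scale * MEV_TO_J / (mass_g * 1e-3)
        return float(per_batch.mean()), float(per_batch.std(ddof=1) / np.sqrt(n_batch))

    for r, name in enumerate(maps.region_names):
        d, se = _dose_and_se(rm_batch[:, r], rm_mass_region[r])
        gpg = d / administered_gbq if administered_gbq else None
        report.regions.append(RegionDose(name, rm_mass_region[r], d, se, gpg))
    d, se = _dose_and_se(rm_batch.sum(axis=1), rm_mass_region.sum())
    gpg = d / administered_gbq if administered_gbq else None
    report.fov = RegionDose("FOV", float(rm_mass_region.sum()), d, se, gpg)
    emitted, deposited, escaped = book.sum(axis=0)
    report.diagnostics = {
        "n_histories": int(n_histories), "seed": int(seed),
        "tia_total_mbqs": tia_total, "n_clamped": maps.n_clamped,
        "mean_emission_energy_mev": mean_e, "photons": bool(photons),
        "energy_emitted_mev": float(emitted),
        "energy_deposited_mev": float(deposited),
        "energy_escaped_mev": float(escaped),
    }
    return dose, report


def run_macro_mc(tia: TiaMap, density: VoxelVolume, spongiosa_masks: dict,
                 site_cf: dict, eaf3: EafTable, decay: DecayData,
                 n_histories: int = 1_000_000, seed: int = 0,
                 photons: bool = False, n_batch: int = 10,
                 administered_gbq: float | None = None,
                 consts: MaterialConstants = MATERIALS
                 ) -> tuple[VoxelVolume, DoseReport]:
    """3-compartment macro/micro MC: reference site cellularities, per-voxel
    BVF from the CT density, activity assumed to originate in RM."""
    if eaf3.n_compartments != 3:
        raise ValueError("run_macro_mc needs a 3-compartment EAF table")
    maps = compartment_maps_from_sites(density, spongiosa_masks, site_cf, consts)
    tumor4 = np.zeros(density.shape, np.uint8)
    return _run_mc(tia, density, maps, tumor4, eaf3, None, decay,
                   n_histories, seed, "MC", photons, n_batch, administered_gbq)


def run_mc_sc_pet(tia_corrected: TiaMap, density: VoxelVolume,
                  rm_mass: VoxelVolume, tumor_mask: RegionMask,
                  site_masks: dict, eaf3: EafTable, eaf4: EafTable,
                  decay: DecayData, n_histories: int = 1_000_000,
                  seed: int = 0, photons: bool = False, n_batch: int = 10,
                  administered_gbq: float | None = None,
                  consts: MaterialConstants = MATERIALS
                  ) -> tuple[VoxelVolume, DoseReport]:
    """SC+PET-informed MC: per-voxel (BVF, CF) inverted from the CT density
    and the sulfur-colloid RM mass; tumor-overlapped spongiosa voxels use
    4-compartment EAFs (50% tumor share) with activity originating in tumor."""
    if eaf4 is None or eaf4.n_compartments != 4:
        raise ValueError("run_mc_sc_pet needs a 4-compartment EAF table")
    maps = compartment_maps_from_sc(density, rm_mass, site_masks, consts)
    tumor4 = (tumor_mask.as_bool() & maps.spongiosa).astype(np.uint8)
    return _run_mc(tia_corrected, density, maps, tumor4, eaf3, eaf4, decay,
                   n_histories, seed, "MC_SC+PET", photons, n_batch,
                   administered_gbq)


# ---------------------------------------------------------------------------
# Partial-volume TIA correction
# ---------------------------------------------------------------------------

def pve_correct_tia(tia: TiaMap, rm_mass: VoxelVolume,
                    blood_tia_conc_rm_mbqs_per_g: float, region_masks: dict,
                    tumor_mask: RegionMask) -> TiaMap:
    """Region-level partial-volume correction of the TIA map.

    Per skeletal region, the blood-expected marrow TIA is
    sum_i [A_tilde]_RM * m_RM,i over marrow (non-tumor) voxels.  If the
    imaged marrow TIA exceeds it, marrow voxels are scaled down uniformly and
    the difference is moved into the region's tumor voxels proportional to
    their TIA (uniformly if the tumor TIA is zero), conserving the region
    total; in a tumor-free region the excess is discarded with a warning.
    If the imaged marrow TIA is lower, marrow voxels are scaled up to the
    blood-derived value (the region total rises by expected - imaged).
    """
    tia.tia.require_same_grid(rm_mass)
    out = np.asarray(tia.tia.data, float).copy()
    tumor = tumor_mask.as_bool()
    for name, mask in region_masks.items():
        reg = mask.as_bool()
        marrow = reg & ~tumor
        tum = reg & tumor
        expected = blood_tia_conc_rm_mbqs_per_g \
            * float(np.asarray(rm_mass.data)[marrow].sum())
        imaged = float(out[marrow].sum())
        if imaged == expected:
            continue
        if imaged > expected:  # spill-out: move the excess into tumor voxels
            excess = imaged - expected
            out[marrow] *= expected / imaged if imaged > 0 else 0.0
            if tum.any():
                t_tia = out[tum]
                t_sum = t_tia.sum()
                w = t_tia / t_sum if t_sum > 0 else np.full(t_tia.size,
                                                            1.0 / t_tia.size)
                out[tum] = t_tia + excess * w
            else:
                log.warning("region %r: excess marrow TIA %.4g MBq·s discarded "
                            "(no tumor voxels)", name, excess)
        else:  # spill-in suspected: trust the blood-derived value
            if imaged > 0:
                out[marrow] *= expected / imaged
            elif marrow.any():
                m = np.asarray(rm_mass.data)[marrow]
                w = m / m.sum() if m.sum() > 0 else np.full(m.size, 1.0 / m.size)
                out[marrow] = expected * w
    vol = tia.tia.with_data(out)
    return TiaMap(vol, tia.model_choice.copy())
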