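"""Spongiosa compartment arithmetic.

The spongiosa of a marrow-bearing skeletal site is modelled as three
compartments — trabecular bone, red marrow (RM) and yellow marrow (YM) —
with the bone volume fraction (BVF) and marrow cellularity fraction (CF)
linking voxel density to composition:

    rho_marrow(CF) = CF * rho_RM + (1 - CF) * rho_YM
    BVF            = (rho_voxel - rho_marrow) / (rho_bone - rho_marrow)

With a sulfur-colloid-derived per-voxel RM mass m_RM the pair (BVF, CF) is
recovered jointly from the voxel density by the closed form

    M   = m_RM / (v_voxel * rho_RM)            # = (1-BVF)*CF
    BVF = (rho_voxel - rho_YM - M*(rho_RM - rho_YM)) / (rho_bone - rho_YM)
    CF  = M / (1 - BVF)

Clamping to the physical/EAF-table domain is counted and reported, never
silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volume_io import RegionMask, VoxelVolume

log = logging.getLogger(__name__)

BVF_CLAMP = (0.0, 0.98)
CF_CLAMP = (1e-3, 0.99)


@dataclass(frozen=True)
class MaterialConstants:
    """Mass densities of the spongiosa constituents, g/mL."""

    rho_rm: float = 1.03
    rho_ym: float = 0.98
    rho_bone: float = 1.92
    rho_tumor: float = 1.00

    def __post_init__(self):
        if not (self.rho_ym < self.rho_tumor <= self.rho_rm < self.rho_bone):
            raise ValueError("densities must satisfy YM < tumor <= RM < bone")


MATERIALS = MaterialConstants()

# Adult reference marrow cellularity per skeletal site (dimensionless).
# Approximate reference-man values; shipped as config defaults and
# overridable via data/materials.yaml.
DEFAULT_SITE_CF = {
    "cervical_spine": 0.70, "thoracic_spine": 0.70, "lumbar_spine": 0.70,
    "sacrum": 0.70, "ribs": 0.70, "sternum": 0.70, "hips": 0.48,
    "clavicles": 0.33, "scapulae": 0.38, "skull": 0.38,
    "humeri": 0.25, "femurs": 0.25,
}

# Age (years) -> reference L2 cellularity, linear interpolation between rows.
DEFAULT_AGE_CF = [(0.0, 0.95), (10.0, 0.80), (20.0, 0.70), (40.0, 0.60),
                  (60.0, 0.50), (80.0, 0.40)]


def load_materials_config(path=None) -> dict:
    """Load material/calibration/cellularity config (packaged default:
    ``data/materials.yaml``) into ready-to-use objects.

    Returns a dict with keys ``materials`` (MaterialConstants),
    ``calibration`` (DensityCalibration), ``site_cf`` (dict) and
    ``age_cf`` (list of (age, cf) pairs).
    """
    import yaml

    if path is None:
        from importlib import resources
        text = (resources.files("marrowdose") / "data"
                / "materials.yaml").read_text()
    else:
        from pathlib import Path
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    dens = raw.get("densities", {})
    cal = raw.get("calibration", {})
    return {
        "materials": MaterialConstants(
            rho_rm=dens.get("rho_rm", 1.03), rho_ym=dens.get("rho_ym", 0.98),
            rho_bone=dens.get("rho_bone", 1.92),
            rho_tumor=dens.get("rho_tumor", 1.00)),
        "calibration": DensityCalibration(
            breakpoint_hu=cal.get("breakpoint_hu", 100.0),
            soft_slope=cal.get("soft_slope", 0.001),
            soft_intercept=cal.get("soft_intercept", 1.0),
            bone_slope=cal.get("bone_slope", 0.0005)),
        "site_cf": dict(raw.get("site_cellularity", DEFAULT_SITE_CF)),
        "age_cf": [tuple(row) for row in
                   raw.get("age_cellularity", DEFAULT_AGE_CF)],
    }


def age_based_cf(age_years: float, table=None) -> float:
    """Reference-region cellularity for a patient age (L2-type curve)."""
    tab = table or DEFAULT_AGE_CF
    ages = np.array([a for a, _ in tab])
    cfs = np.array([c for _, c in tab])
    return float(np.interp(age_years, ages, cfs))


# --------------------------------------------------------------------------
# Density calibration
# --------------------------------------------------------------------------

@dataclass
class DensityCalibration:
    """Bi-linear HU -> density (g/mL) calibration.

    Two segments meet continuously at ``breakpoint_hu``; the default is a
    water-anchored identity-slope soft-tissue segment and a shallower bone
    segment (instrument calibrations are site-specific and configurable).
    """

    breakpoint_hu: float = 100.0
    soft_slope: float = 0.001    # g/mL per HU, anchored at (0 HU, 1.0 g/mL)
    soft_intercept: float = 1.0
    bone_slope: float = 0.0005

    def __post_init__(self):
        if self.soft_slope <= 0 or self.bone_slope <= 0:
            raise ValueError("calibration must be monotone increasing")

    @property
    def _rho_break(self) -> float:
        return self.soft_intercept + self.soft_slope * self.breakpoint_hu

    def density(self, hu):
        hu = np.asarray(hu, dtype=float)
        rho = np.where(
            hu <= self.breakpoint_hu,
            self.soft_intercept + self.soft_slope * hu,
            self._rho_break + self.bone_slope * (hu - self.breakpoint_hu),
        )
        return np.clip(rho, 0.001, 3.0)

    def hu(self, rho):
        """Inverse map (used by the phantom generator)."""
        rho = np.asarray(rho, dtype=float)
        return np.where(
            rho <= self._rho_break,
            (rho - self.soft_intercept) / self.soft_slope,
            self.breakpoint_hu + (rho - self._rho_break) / self.bone_slope,
        )


DEFAULT_CALIBRATION = DensityCalibration()


def hu_to_density(ct_hu: VoxelVolume,
                  calib: DensityCalibration = DEFAULT_CALIBRATION) -> VoxelVolume:
    """Apply the bilinear calibration voxel-wise (requires unit tag HU)."""
    if ct_hu.unit != "HU":
        raise ValueError(f"expected unit 'HU', got {ct_hu.unit!r}")
    return ct_hu.with_data(calib.density(ct_hu.data), unit="g/mL")


# --------------------------------------------------------------------------
# BVF / CF arithmetic
# --------------------------------------------------------------------------

def marrow_density(cf, consts: MaterialConstants = MATERIALS):
    """Marrow density for cellularity cf: cf*rho_RM + (1-cf)*rho_YM."""
    cf = np.asarray(cf, dtype=float)
    if np.any(cf < 0) or np.any(cf > 1):
        raise ValueError("cf must lie in [0, 1]")
    return cf * consts.rho_rm + (1.0 - cf) * consts.rho_ym


def bvf_from_density(rho_voxel, cf, consts: MaterialConstants = MATERIALS):
    """Voxel BVF from density and cellularity, clamped to the table domain.

    Returns ``(bvf, clamped)`` where ``clamped`` flags voxels whose raw value
    fell outside [0, 0.98] (out-of-model densities, e.g. cortical bone).
    """
    rho_voxel = np.asarray(rho_voxel, dtype=float)
    rho_m = marrow_density(cf, consts)
    raw = (rho_voxel - rho_m) / (consts.rho_bone - rho_m)
    bvf = np.clip(raw, *BVF_CLAMP)
    return bvf, raw != bvf


def compose_voxel_density(bvf, cf, consts: MaterialConstants = MATERIALS):
    """Forward composition: rho = BVF*rho_bone + (1-BVF)*rho_marrow(CF)."""
    bvf = np.asarray(bvf, dtype=float)
    return bvf * consts.rho_bone + (1.0 - bvf) * marrow_density(cf, consts)


def invert_cf_bvf(rho_voxel, m_rm_g, v_voxel_ml,
                  consts: MaterialConstants = MATERIALS):
    """Joint (BVF, CF) from voxel density and RM mass (closed form).

    Returns ``(bvf, cf, clamped)``; out-of-model inputs (including
    M = m_RM/(v*rho_RM) >= 1) are clamped to the EAF-table domain and
    flagged.
    """
    rho_voxel = np.asarray(rho_voxel, dtype=float)
    m_rm_g = np.asarray(m_rm_g, dtype=float)
    if np.any(m_rm_g < 0):
        raise ValueError("m_RM must be >= 0")
    m = m_rm_g / (v_voxel_ml * consts.rho_rm)  # = (1-bvf)*cf
    bvf_raw = (rho_voxel - consts.rho_ym - m * (consts.rho_rm - consts.rho_ym)) \
        / (consts.rho_bone - consts.rho_ym)
    bvf = np.clip(bvf_raw, *BVF_CLAMP)
    with np.errstate(divide="ignore", invalid="ignore"):
        cf_raw = np.where(m > 0, m / np.maximum(1.0 - bvf, 1e-12), 0.0)
    cf = np.where(m > 0, np.clip(cf_raw, *CF_CLAMP), 0.0)
    clamped = (bvf_raw != bvf) | ((m > 0) & (cf_raw != cf)) | (m >= 1.0)
    return bvf, cf, clamped


# --------------------------------------------------------------------------
# Reference region and sulfur-colloid RM mass map
# --------------------------------------------------------------------------

def reference_rm_mass(bvf_ref: float, cf_ref: float, v_ref_ml: float,
                      consts: MaterialConstants = MATERIALS) -> float:
    """RM mass (g) in the reference region: (1-BVF)*CF*v*rho_RM."""
    if v_ref_ml <= 0:
        raise ValueError("v_ref must be > 0")
    return (1.0 - bvf_ref) * cf_ref * v_ref_ml * consts.rho_rm


@dataclass
class ReferenceRegion:
    """A tumor-free marrow region with uniform, strong SC uptake used to
    anchor the SC-intensity -> RM-mass scaling."""

    mask: RegionMask
    bvf_ref: float
    cf_ref: float
    v_ref_ml: float
    sc_conc_ref: float  # kBq/mL
    statistic: str = "median"

    @property
    def m_rm_ref_g(self) -> float:
        return reference_rm_mass(self.bvf_ref, self.cf_ref, self.v_ref_ml)


def make_reference_region(mask: RegionMask, density: VoxelVolume,
                          sc: VoxelVolume, cf_ref: float,
                          statistic: str = "median") -> ReferenceRegion:
    """Measure the reference-region quantities from the images."""
    if mask.n_voxels == 0:
        raise ValueError("reference mask is empty")
    sel = mask.as_bool()
    v_vox = density.voxel_volume_ml
    bvf, _ = bvf_from_density(np.asarray(density.data)[sel], cf_ref)
    stat = np.median if statistic == "median" else np.mean
    sc_conc = float(stat(np.asarray(sc.data)[sel]))
    return ReferenceRegion(mask, float(np.mean(bvf)), cf_ref,
                           mask.n_voxels * v_vox, sc_conc, statistic)


def sc_mass_map(sc: VoxelVolume, ref: ReferenceRegion,
                site_masks) -> VoxelVolume:
    """Per-voxel RM mass (g) from the sulfur-colloid image.

    The scaling factor is interpreted as mass per unit activity,
    SF = m_RM,ref / (sc_conc_ref * v_ref), so that a uniform reference
    region reproduces m_RM,ref exactly; masses are evaluated only inside
    the skeletal masks.
    """
    if sc.unit != "kBq/mL":
        raise ValueError(f"expected SC unit 'kBq/mL', got {sc.unit!r}")
    if ref.sc_conc_ref <= 0:
        raise ValueError("reference SC concentration must be > 0")
    sf = ref.m_rm_ref_g / (ref.sc_conc_ref * ref.v_ref_ml)  # g per (kBq/mL * mL)
    skel = _union(site_masks)
    mass = np.where(skel, np.asarray(sc.data, dtype=float)
                    * sc.voxel_volume_ml * sf, 0.0)
    mass = np.maximum(mass, 0.0)
    return sc.with_data(mass, unit="g")


def _union(masks) -> np.ndarray:
    if isinstance(masks, dict):
        masks = list(masks.values())
    out = None
    for m in masks:
        b = m.as_bool() if isinstance(m, RegionMask) else np.asarray(m, bool)
        out = b if out is None else (out | b)
    if out is None:
        raise ValueError("no masks given")
    return out


# --------------------------------------------------------------------------
# PET tumor mask
# --------------------------------------------------------------------------

def tumor_mask_from_pet(suv: VoxelVolume, skeletal_masks,
                        threshold: float = 3.0) -> RegionMask:
    """Voxels inside the skeletal masks with SUV strictly above threshold."""
    if suv.unit != "SUV":
        raise ValueError(f"expected unit 'SUV', got {suv.unit!r}")
    skel = _union(skeletal_masks)
    tumor = skel & (np.asarray(suv.data) > threshold)
    return RegionMask(tumor.astype(np.uint8), "tumor", suv.spacing, suv.origin)


# --------------------------------------------------------------------------
# Compartment maps
# --------------------------------------------------------------------------

@dataclass
class CompartmentMaps:
    """Per-voxel BVF, CF and RM mass on the CT grid, with clamp accounting."""

    bvf: np.ndarray
    cf: np.ndarray
    rm_mass_g: np.ndarray
    spongiosa: np.ndarray  # bool
    n_clamped: int = 0
    region_id: np.ndarray | None = None
    region_names: list = field(default_factory=list)

    def rm_mass_total(self) -> float:
        return float(self.rm_mass_g.sum())


def compartment_maps_from_sites(density: VoxelVolume, site_masks: dict,
                                site_cf: dict,
                                consts: MaterialConstants = MATERIALS
                                ) -> CompartmentMaps:
    """Reference-cellularity route: each site gets its tabulated CF and a
    per-voxel BVF from the CT density (the 3-compartment MC input)."""
    shape = density.shape
    bvf = np.zeros(shape)
    cf = np.zeros(shape)
    spong = np.zeros(shape, bool)
    region_id = np.full(shape, -1, np.int16)
    names = []
    n_clamped = 0
    v_vox = density.voxel_volume_ml
    for idx, (name, mask) in enumerate(site_masks.items()):
        if name not in site_cf:
            raise KeyError(f"no cellularity entry for site {name!r}")
        sel = mask.as_bool()
        cf_site = float(site_cf[name])
        b, clamped = bvf_from_density(np.asarray(density.data)[sel], cf_site, consts)
        bvf[sel] = b
        cf[sel] = cf_site
        spong |= sel
        region_id[sel] = idx
        names.append(name)
        n_clamped += int(np.sum(clamped))
    rm_mass = np.where(spong, (1.0 - bvf) * cf * v_vox * consts.rho_rm, 0.0)
    return CompartmentMaps(bvf, cf, rm_mass, spong, n_clamped, region_id, names)


def compartment_maps_from_sc(density: VoxelVolume, rm_mass: VoxelVolume,
                             site_masks: dict,
                             consts: MaterialConstants = MATERIALS
                             ) -> CompartmentMaps:
    """SC-informed route: per-voxel (BVF, CF) by joint inversion of the CT
    density and the sulfur-colloid RM mass map (the 4-compartment MC input)."""
    density.require_same_grid(rm_mass)
    shape = density.shape
    bvf = np.zeros(shape)
    cf = np.zeros(shape)
    mass = np.zeros(shape)
    spong = np.zeros(shape, bool)
    region_id = np.full(shape, -1, np.int16)
    names = []
    n_clamped = 0
    v_vox = density.voxel_volume_ml
    for idx, (name, mask) in enumerate(site_masks.items()):
        sel = mask.as_bool()
        b, c, clamped = invert_cf_bvf(np.asarray(density.data)[sel],
                                      np.asarray(rm_mass.data)[sel], v_vox, consts)
        bvf[sel] = b
        cf[sel] = c
        mass[sel] = np.asarray(rm_mass.data)[sel]
        spong |= sel
        region_id[sel] = idx
        names.append(name)
        n_clamped += int(np.sum(clamped))
    if n_clamped:
        log.info("invert_cf_bvf clamped %d voxels", n_clamped)
    return CompartmentMaps(bvf, cf, mass, spong, n_clamped, region_id, names)
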