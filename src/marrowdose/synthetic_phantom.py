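"""Self-consistent digital patients for end-to-end testing of the pipeline.

A phantom is a set of co-registered volumes on one grid — CT (HU), density,
serial 177Lu activity-concentration images, a PET SUV map, a 99mTc-sulfur-
colloid map, binary masks (skeletal sites, aorta, reference marrow region)
and a blood-count table — generated from a declarative :class:`PhantomSpec`
with exact ground truth: per-voxel BVF/CF/RM mass, per-voxel analytic TIA,
and the tumor mask.

Voxel density is synthesized by forward-composing the spongiosa model
(rho = BVF*rho_bone + (1-BVF)*rho_marrow(CF)) and mapped to HU through the
inverse of the same bilinear calibration the pipeline applies, so the
forward/backward identity holds to machine precision in the noise-free
phantom.  Imaging degradation (Gaussian PSF blur, then Poisson counting
noise, in that physical order) is optional.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .marrow_model import (DEFAULT_CALIBRATION, MATERIALS, CompartmentMaps,
                           DensityCalibration, MaterialConstants,
                           compose_voxel_density)
from .volume_io import RegionMask, VoxelVolume, write_mask, write_volume

RHO_SOFT = 1.00
RHO_BLOOD = 1.06
LESION_LAMBDA = 1.5e-6  # 1/s, slow tumor washout used to realize lesion TIA


# --- geometric primitives ---------------------------------------------------

@dataclass(frozen=True)
class Box:
    center_mm: tuple
    size_mm: tuple

    def contains(self, xx, yy, zz):
        cx, cy, cz = self.center_mm
        hx, hy, hz = (s / 2.0 for s in self.size_mm)
        return ((np.abs(xx - cx) <= hx) & (np.abs(yy - cy) <= hy)
                & (np.abs(zz - cz) <= hz))


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple
    radius_mm: float

    def contains(self, xx, yy, zz):
        cx, cy, cz = self.center_mm
        return ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
                <= self.radius_mm ** 2)


@dataclass(frozen=True)
class Cylinder:
    center_mm: tuple
    radius_mm: float
    half_length_mm: float
    axis: str = "z"

    def contains(self, xx, yy, zz):
        cx, cy, cz = self.center_mm
        if self.axis == "z":
            rad = (xx - cx) ** 2 + (yy - cy) ** 2
            ax = np.abs(zz - cz)
        elif self.axis == "y":
            rad = (xx - cx) ** 2 + (zz - cz) ** 2
            ax = np.abs(yy - cy)
        else:
            rad = (yy - cy) ** 2 + (zz - cz) ** 2
            ax = np.abs(xx - cx)
        return (rad <= self.radius_mm ** 2) & (ax <= self.half_length_mm)


# --- spec -------------------------------------------------------------------

@dataclass(frozen=True)
class TacSpec:
    """Per-tissue time-activity curve: 'mono' (A0, lam), 'biexp3'
    (A, lam1, lam2) or 'biexp4' (A1, lam1, A2, lam2); amplitudes kBq/mL,
    rates 1/s."""

    model: str
    params: tuple

    def __call__(self, t_s):
        t = np.asarray(t_s, dtype=float)
        if self.model == "mono":
            a0, lam = self.params
            return a0 * np.exp(-lam * t)
        if self.model == "biexp3":
            a, l1, l2 = self.params
            return a * (np.exp(-l1 * t) - np.exp(-l2 * t))
        if self.model == "biexp4":
            a1, l1, a2, l2 = self.params
            return a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t)
        raise ValueError(f"unknown TAC model {self.model!r}")

    @property
    def integral(self) -> float:
        """Analytic time integral, kBq·s/mL."""
        if self.model == "mono":
            a0, lam = self.params
            return a0 / lam
        if self.model == "biexp3":
            a, l1, l2 = self.params
            return a * (1.0 / l1 - 1.0 / l2)
        a1, l1, a2, l2 = self.params
        return a1 / l1 + a2 / l2


@dataclass(frozen=True)
class SiteDef:
    name: str
    shape: object
    cf: float
    bvf: float
    tac: TacSpec

    def __post_init__(self):
        if not (0.0 < self.cf < 1.0):
            raise ValueError(f"site {self.name}: CF must be in (0,1)")
        if not (0.0 <= self.bvf < 1.0):
            raise ValueError(f"site {self.name}: BVF must be in [0,1)")


@dataclass(frozen=True)
class LesionDef:
    center_mm: tuple
    radius_mm: float
    suv: float
    tia_conc_mbqs_per_ml: float
    displace_marrow: bool = False


@dataclass(frozen=True)
class NoiseModel:
    psf_fwhm_mm: float = 0.0
    poisson_scale: float = 0.0  # expected counts per kBq/mL; 0 disables


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple = (32, 32, 48)
    voxel_size_mm: tuple = (4.0, 4.0, 4.0)
    sites: tuple = ()
    lesions: tuple = ()
    aorta: Cylinder | None = None
    blood_curve: TacSpec = TacSpec("biexp4", (20.0, 1e-4, 5.0, 2e-6))
    background_tac: TacSpec = TacSpec("mono", (0.5, 3e-6))
    reference_box: Box | None = None
    reference_site: str = ""
    sc_reference_conc_kbq_ml: float = 7.8
    pet_background_suv: float = 1.0
    noise: NoiseModel = NoiseModel()
    seed: int = 0


def default_phantom_spec(seed: int = 0, lesions: tuple = (),
                         noise: NoiseModel = NoiseModel()) -> PhantomSpec:
    """A desk-scale 'patient': lumbar spine + sacrum + two femurs + aorta on
    a 32x32x48 grid of 4 mm voxels.

    Marrow kinetics are low-amplitude and blood-driven (the tracer has no
    specific marrow uptake), so marrow TIA concentrations are of the order
    of the blood-derived expectation; lesions carry much higher uptake.
    """
    spine = SiteDef("lumbar_spine", Box((64, 64, 120), (28, 28, 120)),
                    cf=0.70, bvf=0.12,
                    tac=TacSpec("biexp3", (1.2, 2e-6, 3e-5)))
    sacrum = SiteDef("sacrum", Box((64, 64, 28), (44, 28, 32)),
                     cf=0.70, bvf=0.17,
                     tac=TacSpec("mono", (2.0, 4e-6)))
    fem_l = SiteDef("femur_left", Cylinder((24, 64, 40), 10, 36),
                    cf=0.25, bvf=0.25, tac=TacSpec("mono", (1.5, 5e-6)))
    fem_r = SiteDef("femur_right", Cylinder((104, 64, 40), 10, 36),
                    cf=0.25, bvf=0.25, tac=TacSpec("mono", (1.5, 5e-6)))
    aorta = Cylinder((64, 30, 120), 9.0, 60.0)
    ref = Box((64, 64, 150), (28, 28, 40))
    return PhantomSpec(sites=(spine, sacrum, fem_l, fem_r), aorta=aorta,
                       reference_box=ref, reference_site="lumbar_spine",
                       lesions=lesions, noise=noise, seed=seed)


# --- bundle -----------------------------------------------------------------

@dataclass
class PhantomBundle:
    spec: PhantomSpec
    ct_hu: VoxelVolume
    density: VoxelVolume
    masks: dict                      # site name -> RegionMask (+ aorta, reference)
    truth: CompartmentMaps
    true_tia: VoxelVolume            # MBq·s per voxel
    tumor_mask: RegionMask
    tac_model: np.ndarray            # per-voxel TAC code (0 mono,1 biexp3,2 biexp4)
    tac_params: np.ndarray           # (4, *grid)
    calibration: DensityCalibration = field(
        default_factory=DensityCalibration)

    @property
    def site_masks(self) -> dict:
        return {k: v for k, v in self.masks.items()
                if k not in ("aorta", "reference")}

    @property
    def site_cf(self) -> dict:
        return {s.name: s.cf for s in self.spec.sites}


_TAC_CODE = {"mono": 0, "biexp3": 1, "biexp4": 2}


def _eval_tac_grid(model, params, t_s):
    out = np.zeros(model.shape)
    mono = model == 0
    out[mono] = params[0][mono] * np.exp(-params[1][mono] * t_s)
    b3 = model == 1
    out[b3] = params[0][b3] * (np.exp(-params[1][b3] * t_s)
                               - np.exp(-params[2][b3] * t_s))
    b4 = model == 2
    out[b4] = (params[0][b4] * np.exp(-params[1][b4] * t_s)
               + params[2][b4] * np.exp(-params[3][b4] * t_s))
    return out


def _tia_grid(model, params):
    out = np.zeros(model.shape)
    mono = model == 0
    out[mono] = params[0][mono] / params[1][mono]
    b3 = model == 1
    out[b3] = params[0][b3] * (1.0 / params[1][b3] - 1.0 / params[2][b3])
    b4 = model == 2
    out[b4] = params[0][b4] / params[1][b4] + params[2][b4] / params[3][b4]
    return out


def build_phantom(spec: PhantomSpec,
                  calib: DensityCalibration = DEFAULT_CALIBRATION,
                  consts: MaterialConstants = MATERIALS) -> PhantomBundle:
    """Voxelize the spec into a fully self-consistent phantom bundle."""
    shape = tuple(spec.grid_shape)
    sp = tuple(spec.voxel_size_mm)
    v_vox_ml = float(np.prod(sp)) / 1000.0
    idx = np.indices(shape, dtype=float)
    xx = (idx[0] + 0.5) * sp[0]
    yy = (idx[1] + 0.5) * sp[1]
    zz = (idx[2] + 0.5) * sp[2]

    density = np.full(shape, RHO_SOFT)
    bvf = np.zeros(shape)
    cf = np.zeros(shape)
    spong = np.zeros(shape, bool)
    tac_model = np.zeros(shape, np.int8)
    tac_params = np.zeros((4,) + shape)
    bg = spec.background_tac
    tac_model[:] = _TAC_CODE[bg.model]
    for i, p in enumerate(bg.params):
        tac_params[i][:] = p

    masks = {}
    for site in spec.sites:
        sel = site.shape.contains(xx, yy, zz)
        for other, m in masks.items():
            if (sel & m.as_bool()).any():
                raise ValueError(
                    f"site primitives overlap: {site.name!r} and {other!r}")
        masks[site.name] = RegionMask(sel.astype(np.uint8), site.name, sp)
        density[sel] = compose_voxel_density(site.bvf, site.cf, consts)
        bvf[sel] = site.bvf
        cf[sel] = site.cf
        spong |= sel
        tac_model[sel] = _TAC_CODE[site.tac.model]
        for i in range(4):
            tac_params[i][sel] = (site.tac.params[i]
                                  if i < len(site.tac.params) else 0.0)

    if spec.aorta is not None:
        sel = spec.aorta.contains(xx, yy, zz)
        if (sel & spong).any():
            raise ValueError("site primitives overlap: 'aorta' and a skeletal site")
        masks["aorta"] = RegionMask(sel.astype(np.uint8), "aorta", sp)
        density[sel] = RHO_BLOOD
        tac_model[sel] = _TAC_CODE[spec.blood_curve.model]
        for i, p in enumerate(spec.blood_curve.params):
            tac_params[i][sel] = p

    tumor = np.zeros(shape, bool)
    for les in spec.lesions:
        sel = Sphere(les.center_mm, les.radius_mm).contains(xx, yy, zz)
        tumor |= sel
        tac_model[sel] = _TAC_CODE["mono"]
        tac_params[0][sel] = les.tia_conc_mbqs_per_ml * LESION_LAMBDA * 1e3  # kBq/mL
        tac_params[1][sel] = LESION_LAMBDA
        if les.displace_marrow:
            cf[sel & spong] = 0.0

    rm_mass = np.where(spong, (1.0 - bvf) * cf * v_vox_ml * consts.rho_rm, 0.0)
    truth = CompartmentMaps(bvf, cf, rm_mass, spong)

    if spec.reference_box is not None:
        ref_sel = spec.reference_box.contains(xx, yy, zz)
        if spec.reference_site:
            ref_sel &= masks[spec.reference_site].as_bool()
        ref_sel &= ~tumor
        masks["reference"] = RegionMask(ref_sel.astype(np.uint8), "reference", sp)

    hu = calib.hu(density)
    ct = VoxelVolume(hu, sp, "HU")
    dens_vol = VoxelVolume(calib.density(hu), sp, "g/mL")

    tia_conc = _tia_grid(tac_model, tac_params)  # kBq·s/mL
    true_tia = VoxelVolume(np.maximum(tia_conc, 0.0) * v_vox_ml * 1e-3,
                           sp, "MBq·s")
    return PhantomBundle(spec, ct, dens_vol, masks, truth, true_tia,
                         RegionMask(tumor.astype(np.uint8), "tumor", sp),
                         tac_model, tac_params, calib)


# --- simulated acquisitions -------------------------------------------------

def simulate_timepoint_images(bundle: PhantomBundle, times_h,
                              noise: NoiseModel | None = None,
                              seed: int | None = None) -> list:
    """Serial 177Lu activity-concentration images (kBq/mL) at ``times_h``.

    Noise-free mode returns the exact TAC values; otherwise the image is
    blurred with the Gaussian PSF and then Poisson counting noise is applied
    (resolution loss precedes counting noise physically).
    """
    times_h = list(times_h)
    if len(times_h) < 3:
        raise ValueError("need >= 3 timepoints (downstream fits require it)")
    if any(t2 <= t1 for t1, t2 in zip(times_h, times_h[1:])):
        raise ValueError("times must be strictly increasing")
    noise = noise if noise is not None else bundle.spec.noise
    rng = np.random.default_rng(bundle.spec.seed if seed is None else seed)
    sp = bundle.ct_hu.spacing
    out = []
    for t_h in times_h:
        img = _eval_tac_grid(bundle.tac_model, bundle.tac_params, t_h * 3600.0)
        if noise.psf_fwhm_mm > 0:
            sigma = [noise.psf_fwhm_mm / 2.3548 / s for s in sp]
            img = gaussian_filter(img, sigma)
        if noise.poisson_scale > 0:
            img = rng.poisson(np.maximum(img, 0.0) * noise.poisson_scale) \
                / noise.poisson_scale
        out.append(VoxelVolume(img, sp, "kBq/mL"))
    return out


def simulate_sc_and_pet(bundle: PhantomBundle,
                        noise: NoiseModel | None = None,
                        seed: int | None = None):
    """Sulfur-colloid (kBq/mL) and PET SUV maps.

    SC is proportional to the truth RM mass per voxel volume, scaled so the
    reference-region median equals ``sc_reference_conc_kbq_ml``; PET is the
    background SUV everywhere except inside lesions.
    """
    ref = bundle.masks.get("reference")
    if ref is None or ref.n_voxels == 0:
        raise ValueError("phantom has no (non-empty) reference region")
    sp = bundle.ct_hu.spacing
    v_vox = bundle.ct_hu.voxel_volume_ml
    conc = bundle.truth.rm_mass_g / v_vox  # g/mL, proportional surrogate
    ref_med = float(np.median(conc[ref.as_bool()]))
    if ref_med <= 0:
        raise ValueError("reference region has zero truth RM mass")
    sc = conc * (bundle.spec.sc_reference_conc_kbq_ml / ref_med)
    suv = np.full(bundle.ct_hu.shape, bundle.spec.pet_background_suv)
    idx = np.indices(bundle.ct_hu.shape, dtype=float)
    xx = (idx[0] + 0.5) * sp[0]
    yy = (idx[1] + 0.5) * sp[1]
    zz = (idx[2] + 0.5) * sp[2]
    for les in bundle.spec.lesions:
        suv[Sphere(les.center_mm, les.radius_mm).contains(xx, yy, zz)] = les.suv
    noise = noise if noise is not None else NoiseModel()
    if noise.psf_fwhm_mm > 0 or noise.poisson_scale > 0:
        rng = np.random.default_rng(
            (bundle.spec.seed if seed is None else seed) + 1)
        if noise.psf_fwhm_mm > 0:
            sigma = [noise.psf_fwhm_mm / 2.3548 / s for s in sp]
            sc = gaussian_filter(sc, sigma)
        if noise.poisson_scale > 0:
            sc = rng.poisson(np.maximum(sc, 0.0) * noise.poisson_scale) \
                / noise.poisson_scale
    return (VoxelVolume(sc, sp, "kBq/mL"), VoxelVolume(suv, sp, "SUV"))


# --- blood counts -----------------------------------------------------------

BLOOD_MARKERS = {
    "platelets": 250.0, "neutrophils": 4.5, "lymphocytes": 1.8,
    "white_cells": 7.0, "hemoglobin": 13.5,
}


def simulate_blood_panel(doses_gy, seed: int = 0,
                         followup_weeks: float = 6.0,
                         sensitivity: float = 0.08,
                         cv: float = 0.05) -> pd.DataFrame:
    """Baseline and follow-up blood counts for subjects with given RM doses.

    Counts decline from baseline proportionally to dose (fractional drop
    ``sensitivity`` per Gy, floored at 85% total drop) with lognormal
    measurement noise — enough structure to exercise the dose-toxicity
    correlation layer with a known negative association.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for subj, dose in enumerate(np.asarray(doses_gy, float)):
        for marker, base in BLOOD_MARKERS.items():
            b = base * float(rng.lognormal(0.0, cv))
            drop = min(sensitivity * dose, 0.85)
            f = b * (1.0 - drop) * float(rng.lognormal(0.0, cv))
            rows.append((f"P{subj + 1}", marker, 0.0, b))
            rows.append((f"P{subj + 1}", marker, followup_weeks, f))
    return pd.DataFrame(rows, columns=["subject", "marker", "time_weeks",
                                       "value"])


# --- serialization ----------------------------------------------------------

def write_phantom(bundle: PhantomBundle, outdir,
                  times_h=(1.0, 36.0, 84.0, 132.0)) -> dict:
    """Write all phantom volumes as NIfTI plus a manifest JSON; returns the
    manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def _put(name, writer, obj):
        path = outdir / name
        writer(obj, path)
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    _put("ct_hu.nii", write_volume, bundle.ct_hu)
    _put("density.nii", write_volume, bundle.density)
    _put("true_tia.nii", write_volume, bundle.true_tia)
    _put("tumor_mask.nii", write_mask, bundle.tumor_mask)
    for name, mask in bundle.masks.items():
        _put(f"mask_{name}.nii", write_mask, mask)
    series = simulate_timepoint_images(bundle, times_h)
    for t_h, vol in zip(times_h, series):
        _put(f"lu177_{t_h:g}h.nii", write_volume, vol)
    sc, pet = simulate_sc_and_pet(bundle)
    _put("sc.nii", write_volume, sc)
    _put("pet_suv.nii", write_volume, pet)
    manifest = {"seed": bundle.spec.seed, "times_h": list(times_h),
                "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
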