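"""Voxel volumes, NIfTI I/O, resampling, and spongiosa mask refinement.

All stages of the pipeline exchange data as :class:`VoxelVolume` — a 3-D
scalar field with voxel spacing (mm), origin (mm) and a physical-unit tag.
Grids are never regridded implicitly: arithmetic and the dose engines demand
identical grids, and :func:`resample_to_reference` is the single explicit
regridding step (silent misregistration is the dominant failure mode in
voxel dosimetry pipelines).

Units are stored in the NIfTI ``descrip`` header field as ``unit=<tag>`` and
mirrored in an optional JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.morphology import ball, erosion, remove_small_objects

log = logging.getLogger(__name__)

VALID_UNITS = {"HU", "g/mL", "Bq/mL", "kBq/mL", "SUV", "MBq·s", "MBq·s/mL",
               "g", "Gy", "1"}


class GridMismatchError(ValueError):
    pass


@dataclass
class VoxelVolume:
    """A 3-D scalar field with grid metadata and a physical-unit tag."""

    data: np.ndarray
    spacing: tuple  # mm
    unit: str
    origin: tuple = (0.0, 0.0, 0.0)  # mm

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VoxelVolume data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be > 0")
        if not self.unit:
            raise ValueError("unit tag is required")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def grid(self):
        return (self.data.shape, self.spacing, self.origin)

    def same_grid(self, other: "VoxelVolume") -> bool:
        return (self.data.shape == other.data.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def require_same_grid(self, other: "VoxelVolume"):
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.grid()} vs {other.grid()}")

    def with_data(self, data, unit=None) -> "VoxelVolume":
        return replace(self, data=np.asarray(data), unit=unit or self.unit)


@dataclass
class RegionMask:
    """A named binary mask on the same grid convention as VoxelVolume."""

    data: np.ndarray
    name: str
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, [0, 1])):
            # accept common {0,255} dialect with a warning
            if np.all(np.isin(vals, [0, 255])):
                log.warning("mask %r uses {0,255}; normalizing to {0,1}", self.name)
                arr = (arr > 0).astype(np.uint8)
            else:
                raise ValueError(f"mask {self.name!r} is not binary: {vals[:5]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def to_volume(self) -> VoxelVolume:
        return VoxelVolume(self.data.astype(np.uint8), self.spacing, "1",
                           self.origin)


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def _affine(spacing, origin):
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: VoxelVolume, path, sidecar: bool = True):
    """Write a volume as NIfTI-1 with the unit tag in the header descrip."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    img.header["descrip"] = f"unit={vol.unit}".encode()[:79]
    nib.save(img, str(path))
    if sidecar:
        side = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
        Path(str(side) + ".json").write_text(json.dumps({"unit": vol.unit}))


def read_volume(path, unit: str | None = None) -> VoxelVolume:
    """Read a NIfTI volume; the unit tag comes from the header descrip, the
    JSON sidecar, or the ``unit`` argument (in that order of precedence for
    missing values)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    tag = None
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="ignore")
    if descrip.startswith("unit="):
        tag = descrip[5:]
    if tag is None:
        side = path.with_suffix("").with_suffix("")
        sidecar = Path(str(side) + ".json")
        if sidecar.exists():
            tag = json.loads(sidecar.read_text()).get("unit")
    if tag is None:
        tag = unit
    if tag is None:
        raise ValueError(f"{path}: unit tag missing and not inferable")
    return VoxelVolume(data, spacing, tag, origin)


def read_mask(path, name: str | None = None) -> RegionMask:
    vol = read_volume(path, unit="1")
    return RegionMask(vol.data, name or Path(path).stem, vol.spacing, vol.origin)


def write_mask(mask: RegionMask, path):
    write_volume(mask.to_volume(), path)


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def resample_to_reference(vol: VoxelVolume, ref, mode: str = "trilinear",
                          preserve: str = "concentration") -> VoxelVolume:
    """Resample ``vol`` onto the grid of ``ref`` (a VoxelVolume or a
    ``(shape, spacing, origin)`` triple).

    ``preserve='concentration'`` interpolates values unchanged;
    ``preserve='total_amount'`` additionally multiplies by the voxel-volume
    ratio so that per-voxel amounts (e.g. MBq·s per voxel) keep their spatial
    integral.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    if preserve not in ("concentration", "total_amount"):
        raise ValueError(f"unknown preserve option {preserve!r}")
    if isinstance(ref, VoxelVolume):
        shape, spacing, origin = ref.grid()
    else:
        shape, spacing, origin = ref
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(float(o) for o in origin)

    matrix = np.diag([spacing[i] / vol.spacing[i] for i in range(3)])
    offset = [(origin[i] - vol.origin[i]) / vol.spacing[i] for i in range(3)]
    order = 0 if mode == "nearest" else 1
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float), matrix, offset=offset,
        output_shape=shape, order=order, mode="constant", cval=0.0)
    if preserve == "total_amount":
        ratio = np.prod(spacing) / np.prod(vol.spacing)
        out = out * ratio
    return VoxelVolume(out, spacing, vol.unit, origin)


# --------------------------------------------------------------------------
# Spongiosa refinement
# --------------------------------------------------------------------------

@dataclass
class RefineParams:
    """Morphological refinement parameters (config, not paper constants).

    ``hu_threshold``: voxels at/above this HU are treated as cortical bone and
    removed.  ``erosion_mm``: contraction radius.  ``min_island_voxels``:
    islands strictly smaller than this are dropped.
    """

    hu_threshold: float = 800.0
    erosion_mm: float = 0.0
    min_island_voxels: int = 0


def refine_spongiosa_mask(site_mask: RegionMask, ct_hu: VoxelVolume,
                          params: RefineParams = RefineParams()) -> RegionMask:
    """Refine a skeletal-site mask to spongiosa only: contract, remove
    high-HU (cortical) voxels, drop small disconnected islands."""
    if site_mask.n_voxels == 0:
        raise ValueError(f"site mask {site_mask.name!r} is empty")
    if site_mask.data.shape != ct_hu.data.shape:
        raise GridMismatchError("site mask and CT are on different grids")
    out = site_mask.as_bool()
    if params.erosion_mm > 0:
        radius_vox = max(1, int(round(params.erosion_mm / min(ct_hu.spacing))))
        out = erosion(out, ball(radius_vox))
    out = out & (np.asarray(ct_hu.data) < params.hu_threshold)
    if params.min_island_voxels > 1:
        out = remove_small_objects(out, min_size=params.min_island_voxels)
    if not out.any():
        raise ValueError(
            f"refinement emptied mask {site_mask.name!r}; relax hu_threshold "
            f"({params.hu_threshold}) or erosion ({params.erosion_mm} mm)")
    return RegionMask(out.astype(np.uint8), site_mask.name + "_spongiosa",
                      site_mask.spacing, site_mask.origin)
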