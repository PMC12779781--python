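"""Micro-scale spongiosa geometries and electron energy absorption fractions.

Trabecular spongiosa is represented on a 50 µm subvoxel lattice with three
(bone, RM, YM) or four (plus tumor) compartments.  Bone is placed by
thresholding a smoothed Gaussian random field at the quantile that realizes
the requested bone volume fraction, which yields trabecular-like connected
structures; tumor (when present) occupies a random half of the non-bone
subvoxels, and the remaining marrow subvoxels are split into RM/YM at the
requested cellularity with exact counts.

For each table node (energy, BVF, CF) electrons are transported with the
condensed-history kernel from three source classes — initial emission
(born in RM, or in tumor for the 4-compartment model), boundary crossing
(entering through a lattice face), and secondary (uniform start) — and the
fraction of the initial energy absorbed per compartment is tabulated
together with its Monte Carlo standard error.  Queries interpolate
trilinearly in (log energy, BVF, CF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .physics import csda_range_mm
from .transport import MAT_RHO, MAT_SPR, eaf_interp, micro_transport
from .physics import _LOG_E, _LOG_S

SUBVOXEL_MM = 0.05
SOURCE_CLASSES = ("initial_emission", "boundary_crossing", "secondary")
COMPARTMENTS3 = ("bone", "rm", "ym", "escape")
COMPARTMENTS4 = ("bone", "rm", "ym", "tumor", "escape")

# lattice sizing: >= 2x CSDA range per side, within [48, 160] subvoxels
# (the cap, 8 mm, is the scale of a real spongiosa block; above ~1.1 MeV part
# of the escape fraction reflects the finite block)
LATTICE_MIN = 48
LATTICE_CAP = 160

_MAT_CODE = {"bone": 0, "rm": 1, "ym": 2, "tumor": 3}


@dataclass
class MicroGeometry:
    """A labelled subvoxel lattice (codes: 0 bone, 1 RM, 2 YM, 3 tumor)."""

    lattice: np.ndarray
    subvoxel_mm: float
    bvf: float
    cf: float
    tumor_fraction: float
    seed: int

    def realized_fractions(self):
        lab = self.lattice
        n = lab.size
        n_bone = int(np.sum(lab == 0))
        n_t = int(np.sum(lab == 3))
        n_rm = int(np.sum(lab == 1))
        n_ym = int(np.sum(lab == 2))
        marrow = max(n_rm + n_ym, 1)
        return {
            "bvf": n_bone / n,
            "tumor_of_nonbone": n_t / max(n - n_bone, 1),
            "cf": n_rm / marrow,
        }

    def mass_fractions(self):
        """Mass fraction per compartment (bone, rm, ym, tumor)."""
        counts = np.array([np.sum(self.lattice == c) for c in range(4)], float)
        masses = counts * MAT_RHO
        return masses / masses.sum()


def lattice_side_for_energy(energy_kev: float) -> int:
    side = int(np.ceil(2.0 * csda_range_mm(energy_kev) / SUBVOXEL_MM))
    return int(np.clip(side, LATTICE_MIN, LATTICE_CAP))


def build_micro_geometry(bvf: float, cf: float, tumor_fraction: float,
                         lattice_size: int, seed: int,
                         smooth_sigma: float = 2.0,
                         bone_mode: str = "field") -> MicroGeometry:
    """Build one micro-scale spongiosa realization.

    ``bone_mode='field'`` thresholds a smoothed Gaussian random field at the
    BVF quantile (trabecular-like connectivity); ``'iid'`` assigns bone
    subvoxels independently.
    """
    if not (0.0 <= bvf < 1.0):
        raise ValueError("bvf must be in [0, 1)")
    if not (0.0 <= cf <= 1.0):
        raise ValueError("cf must be in [0, 1]")
    if tumor_fraction not in (0.0, 0.5):
        raise ValueError("tumor_fraction must be 0 or 0.5")
    n = int(lattice_size)
    if n < 16 or n ** 3 < 100:
        raise ValueError("lattice too small to realize fractions within 1%")
    rng = np.random.default_rng(seed)
    lab = np.full((n, n, n), 2, np.int8)  # start as YM
    nvox = n ** 3
    if bvf > 0:
        if bone_mode == "field":
            fld = rng.standard_normal((n, n, n)).astype(np.float32)
            gaussian_filter(fld, smooth_sigma, output=fld)
            thr = np.quantile(fld, 1.0 - bvf)
            bone = fld >= thr
        elif bone_mode == "iid":
            bone = rng.random((n, n, n)) < bvf
        else:
            raise ValueError(f"unknown bone_mode {bone_mode!r}")
        lab[bone] = 0
    nonbone = np.flatnonzero(lab.ravel() != 0)
    perm = rng.permutation(nonbone)
    n_tumor = int(round(tumor_fraction * perm.size))
    flat = lab.ravel()
    flat[perm[:n_tumor]] = 3
    marrow = perm[n_tumor:]
    n_rm = int(round(cf * marrow.size))
    flat[marrow[:n_rm]] = 1  # marrow order already randomized by perm
    geom = MicroGeometry(lab, SUBVOXEL_MM, bvf, cf, tumor_fraction, seed)
    real = geom.realized_fractions()
    if abs(real["bvf"] - bvf) > 0.01:
        raise ValueError("lattice too small: realized BVF off by > 1%")
    if cf > 0 and abs(real["cf"] - cf) > 0.01:
        raise ValueError("lattice too small: realized CF off by > 1%")
    return geom


def _source_label(geom: MicroGeometry) -> int:
    return _MAT_CODE["tumor"] if geom.tumor_fraction > 0 else _MAT_CODE["rm"]


def transport_electron(geom: MicroGeometry, energy_kev: float,
                       source_class: str, seed: int,
                       n_histories: int = 1, n_batch: int = 1) -> dict:
    """Transport electron histories through a micro geometry.

    Returns summed energy (MeV) per compartment plus ``escape``;
    per history, deposited + escaped equals the initial energy exactly.
    """
    if not (10.0 <= energy_kev <= 2500.0):
        raise ValueError("energy must be within 10-2500 keV")
    cls = SOURCE_CLASSES.index(source_class)
    tal = micro_transport(geom.lattice, geom.subvoxel_mm, energy_kev * 1e-3,
                          cls, _source_label(geom), n_histories, n_batch,
                          int(seed) % (2 ** 31 - 1), _LOG_E, _LOG_S,
                          MAT_RHO, MAT_SPR)
    total = tal.sum(axis=0)
    names = ["bone", "rm", "ym", "tumor", "escape"]
    out = {nm: float(total[i]) for i, nm in enumerate(names)}
    out["_batches"] = tal
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def desk_grid():
    """The desk-scale node grid: 5 BVFs x 4 CFs x 8 log-spaced energies."""
    return dict(
        energies_kev=np.round(np.logspace(np.log10(10.0), np.log10(2500.0), 8), 1),
        bvfs=np.array([0.03, 0.08, 0.17, 0.26, 0.35]),
        cfs=np.array([0.01, 0.33, 0.66, 0.99]),
    )


def full_grid():
    """The full-resolution grid: 12 BVFs (3-35%), 11 CFs (1-99%),
    37 energies (10 keV-2.5 MeV, log-spaced)."""
    return dict(
        energies_kev=np.logspace(np.log10(10.0), np.log10(2500.0), 37),
        bvfs=np.linspace(0.03, 0.35, 12),
        cfs=np.linspace(0.01, 0.99, 11),
    )


@dataclass
class EafTable:
    """EAF lookup table.

    ``values`` has shape (nE, nBVF, nCF, 3 source classes, n_comp+1) with the
    escape fraction last; each node row sums to 1 exactly.  ``stderr`` holds
    the per-node Monte Carlo standard errors.
    """

    energies_kev: np.ndarray
    bvfs: np.ndarray
    cfs: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    n_compartments: int  # 3 or 4
    histories_per_node: int
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def compartments(self):
        return COMPARTMENTS3 if self.n_compartments == 3 else COMPARTMENTS4

    @property
    def log_energies(self):
        return np.log10(self.energies_kev)

    def kernel_values(self) -> np.ndarray:
        """Values padded to 5 columns (bone, rm, ym, tumor, escape) for the
        macro kernel, escape last."""
        v = self.values
        if self.n_compartments == 4:
            return np.ascontiguousarray(v)
        out = np.zeros(v.shape[:4] + (5,))
        out[..., :3] = v[..., :3]
        out[..., 4] = v[..., 3]
        return np.ascontiguousarray(out)

    def save(self, path):
        path = Path(path)
        obj = {
            "energies_kev": self.energies_kev.tolist(),
            "bvfs": self.bvfs.tolist(),
            "cfs": self.cfs.tolist(),
            "values": self.values.tolist(),
            "stderr": self.stderr.tolist(),
            "n_compartments": self.n_compartments,
            "histories_per_node": self.histories_per_node,
            "seed": self.seed,
            "metadata": self.metadata,
        }
        path.write_text(json.dumps(obj))

    @classmethod
    def load(cls, path) -> "EafTable":
        obj = json.loads(Path(path).read_text())
        return cls(
            np.array(obj["energies_kev"]), np.array(obj["bvfs"]),
            np.array(obj["cfs"]), np.array(obj["values"]),
            np.array(obj["stderr"]), obj["n_compartments"],
            obj["histories_per_node"], obj["seed"], obj.get("metadata", {}))


def build_eaf_table(grid_spec=None, histories_per_node: int = 2000,
                    seed: int = 0, compartments: int = 3,
                    n_batch: int = 10, bone_mode: str = "field",
                    tumor_fraction: float | None = None) -> EafTable:
    """Monte Carlo compile of an EAF table over the node grid.

    A fresh micro geometry is built per (BVF, CF, energy) node; all three
    source classes are simulated with ``histories_per_node`` histories each.
    The 4-compartment model defaults to the 50% tumor share of non-bone
    spongiosa; ``tumor_fraction=0`` reduces it to the 3-compartment
    geometry (a nesting check).
    """
    if histories_per_node < 100:
        raise ValueError("histories_per_node must be >= 100")
    if compartments not in (3, 4):
        raise ValueError("compartments must be 3 or 4")
    grid = grid_spec or desk_grid()
    energies = np.asarray(grid["energies_kev"], float)
    bvfs = np.asarray(grid["bvfs"], float)
    cfs = np.asarray(grid["cfs"], float)
    if tumor_fraction is None:
        tumor_fraction = 0.5 if compartments == 4 else 0.0
    ncomp_out = compartments + 1
    values = np.zeros((energies.size, bvfs.size, cfs.size, 3, ncomp_out))
    stderr = np.zeros_like(values)
    col_map = [0, 1, 2, 3, 4] if compartments == 4 else [0, 1, 2, 4]
    ss = np.random.SeedSequence(seed)
    node_seeds = ss.generate_state(energies.size * bvfs.size * cfs.size * 4)
    node = 0
    for ie, e_kev in enumerate(energies):
        side = lattice_side_for_energy(e_kev)
        for ib, bvf in enumerate(bvfs):
            for ic, cf in enumerate(cfs):
                geom = build_micro_geometry(
                    bvf, cf, tumor_fraction, side,
                    int(node_seeds[node] % (2 ** 31 - 1)),
                    bone_mode=bone_mode)
                for cls in range(3):
                    tal = micro_transport(
                        geom.lattice, geom.subvoxel_mm, e_kev * 1e-3, cls,
                        _source_label(geom), histories_per_node, n_batch,
                        int(node_seeds[node + cls + 1] % (2 ** 31 - 1)),
                        _LOG_E, _LOG_S, MAT_RHO, MAT_SPR)
                    e_batch = histories_per_node / n_batch * e_kev * 1e-3
                    frac = tal / e_batch  # per-batch EAFs
                    mean = frac.mean(axis=0)
                    se = frac.std(axis=0, ddof=1) / np.sqrt(n_batch)
                    for c_out, c_in in enumerate(col_map):
                        values[ie, ib, ic, cls, c_out] = mean[c_in]
                        stderr[ie, ib, ic, cls, c_out] = se[c_in]
                node += 4
    return EafTable(energies, bvfs, cfs, values, stderr, compartments,
                    histories_per_node, seed,
                    metadata={"bone_mode": bone_mode,
                              "lattice_cap": LATTICE_CAP})


def interpolate_eaf(table: EafTable, energy_kev: float, bvf: float, cf: float,
                    source_class: str = "initial_emission") -> dict:
    """Per-compartment EAFs at an arbitrary query point (clamped to the
    table bounds), renormalized so compartments + escape sum to 1."""
    cls = SOURCE_CLASSES.index(source_class)
    out = np.empty(table.values.shape[4])
    eaf_interp(np.ascontiguousarray(table.values), table.log_energies,
               table.bvfs, table.cfs, energy_kev * 1e-3,
               float(bvf), float(cf), cls, out)
    return dict(zip(table.compartments, (float(v) for v in out)))
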