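"""Condensed-history electron transport kernels (numba).

A deliberately simple transport model shared by the micro-scale spongiosa
EAF builder and the macro voxel dose engine:

* continuous slowing-down energy loss from the packaged water stopping-power
  table, scaled by per-material mass-stopping ratio and density;
* fixed fractional-energy steps (5% of the current energy), capped at the
  local cell size so deposition is resolved at the lattice scale;
* isotropic direction resampling each step;
* energy below a 1 keV cutoff is deposited locally; energy crossing the open
  boundary is tallied as escape.

Every history conserves energy exactly by construction:
deposited + escaped == initial.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .physics import _LOG_E, _LOG_S, MATERIAL_DENSITY, MATERIAL_S_RATIO

E_CUT_MEV = 0.001
FRAC_STEP = 0.05


@njit(cache=False)
def _stop_water_nb(e_mev, log_e, log_s):
    """Water collision mass stopping power, MeV cm^2/g (log-log interp)."""
    x = np.log10(e_mev * 1000.0)
    n = log_e.size
    if x <= log_e[0]:
        x = log_e[0]
    if x >= log_e[n - 1]:
        x = log_e[n - 1]
    i = 0
    while i < n - 2 and log_e[i + 1] < x:
        i += 1
    w = (x - log_e[i]) / (log_e[i + 1] - log_e[i])
    return 10.0 ** (log_s[i] * (1.0 - w) + log_s[i + 1] * w)


@njit(cache=False)
def _isotropic():
    mu = 2.0 * np.random.random() - 1.0
    phi = 2.0 * np.pi * np.random.random()
    s = np.sqrt(max(1.0 - mu * mu, 0.0))
    return s * np.cos(phi), s * np.sin(phi), mu


# ---------------------------------------------------------------------------
# Micro-scale lattice transport (EAF generation)
# ---------------------------------------------------------------------------

@njit(cache=False)
def micro_transport(labels, sub_mm, e0_mev, source_class, src_label,
                    n_hist, n_batch, seed, log_e, log_s, mat_rho, mat_spr):
    """Transport ``n_hist`` electrons of energy ``e0_mev`` through a labelled
    subvoxel lattice; returns per-batch energy tallies with columns
    (bone, RM, YM, tumor, escape) in MeV."""
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    lx, ly, lz = nx * sub_mm, ny * sub_mm, nz * sub_mm
    tal = np.zeros((n_batch, 5))
    for h in range(n_hist):
        b = h % n_batch
        # --- source position and direction
        if source_class == 0:  # initial emission, inside src_label subvoxels
            for _ in range(1000000):
                i = int(np.random.random() * nx)
                j = int(np.random.random() * ny)
                k = int(np.random.random() * nz)
                if labels[i, j, k] == src_label:
                    break
            x = (i + np.random.random()) * sub_mm
            y = (j + np.random.random()) * sub_mm
            z = (k + np.random.random()) * sub_mm
            ux, uy, uz = _isotropic()
        elif source_class == 1:  # boundary crossing, inward from a face
            face = int(np.random.random() * 6)
            x = np.random.random() * lx
            y = np.random.random() * ly
            z = np.random.random() * lz
            ux, uy, uz = _isotropic()
            if face == 0:
                x = 1e-6
                ux = abs(ux)
            elif face == 1:
                x = lx - 1e-6
                ux = -abs(ux)
            elif face == 2:
                y = 1e-6
                uy = abs(uy)
            elif face == 3:
                y = ly - 1e-6
                uy = -abs(uy)
            elif face == 4:
                z = 1e-6
                uz = abs(uz)
            else:
                z = lz - 1e-6
                uz = -abs(uz)
        else:  # secondary: uniform anywhere in the lattice
            x = np.random.random() * lx
            y = np.random.random() * ly
            z = np.random.random() * lz
            ux, uy, uz = _isotropic()
        # --- condensed-history walk
        e = e0_mev
        while True:
            i = int(x / sub_mm)
            j = int(y / sub_mm)
            k = int(z / sub_mm)
            if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
                tal[b, 4] += e
                break
            m = labels[i, j, k]
            s_lin = (_stop_water_nb(e, log_e, log_s) * mat_spr[m]
                     * mat_rho[m] / 10.0)  # MeV/mm
            ds = FRAC_STEP * e / s_lin
            if ds > sub_mm:
                ds = sub_mm
            de = s_lin * ds
            if e - de <= E_CUT_MEV:
                tal[b, m] += e
                break
            tal[b, m] += de
            e -= de
            ux, uy, uz = _isotropic()
            x += ds * ux
            y += ds * uy
            z += ds * uz
    return tal


# ---------------------------------------------------------------------------
# EAF table lookup (shared by python wrapper and macro kernel)
# ---------------------------------------------------------------------------

@njit(cache=False)
def eaf_interp(vals, loge_ax, bvf_ax, cf_ax, e_mev, bvf, cf, cls, out):
    """Trilinear interpolation in (log E, BVF, CF); ``out`` receives the
    per-compartment fractions (escape last) renormalized to sum to 1."""
    ncomp = vals.shape[4]
    x = np.log10(e_mev * 1000.0)
    axes = (loge_ax, bvf_ax, cf_ax)
    idx = np.empty(3, np.int64)
    wgt = np.empty(3)
    q = np.empty(3)
    q[0] = x
    q[1] = bvf
    q[2] = cf
    for a in range(3):
        ax = axes[a]
        n = ax.size
        if n == 1 or q[a] <= ax[0]:
            idx[a] = 0
            wgt[a] = 0.0
        elif q[a] >= ax[n - 1]:
            idx[a] = n - 2
            wgt[a] = 1.0
        else:
            i = 0
            while ax[i + 1] < q[a]:
                i += 1
            idx[a] = i
            wgt[a] = (q[a] - ax[i]) / (ax[i + 1] - ax[i])
    for c in range(ncomp):
        v = 0.0
        for di in range(2):
            ii = min(idx[0] + di, loge_ax.size - 1)
            wi = wgt[0] if di == 1 else 1.0 - wgt[0]
            for dj in range(2):
                jj = min(idx[1] + dj, bvf_ax.size - 1)
                wj = wgt[1] if dj == 1 else 1.0 - wgt[1]
                for dk in range(2):
                    kk = min(idx[2] + dk, cf_ax.size - 1)
                    wk = wgt[2] if dk == 1 else 1.0 - wgt[2]
                    v += wi * wj * wk * vals[ii, jj, kk, cls, c]
        out[c] = v
    s = 0.0
    for c in range(ncomp):
        s += out[c]
    if s > 0.0:
        for c in range(ncomp):
            out[c] /= s


# ---------------------------------------------------------------------------
# Macro voxel transport
# ---------------------------------------------------------------------------

@njit(cache=False)
def _exit_distance(x, y, z, ux, uy, uz, i, j, k, sx, sy, sz):
    t = 1e30
    if ux > 0.0:
        t = min(t, ((i + 1) * sx - x) / ux)
    elif ux < 0.0:
        t = min(t, (i * sx - x) / ux)
    if uy > 0.0:
        t = min(t, ((j + 1) * sy - y) / uy)
    elif uy < 0.0:
        t = min(t, (j * sy - y) / uy)
    if uz > 0.0:
        t = min(t, ((k + 1) * sz - z) / uz)
    elif uz < 0.0:
        t = min(t, (k * sz - z) / uz)
    return t


@njit(cache=False)
def macro_transport(density, spong, tumor4, region, bvf, cf,
                    tia_cdf, beta_cdf, beta_e,
                    vals3, le3, ba3, ca3, vals4, le4, ba4, ca4, has4,
                    sx, sy, sz, n_hist, n_batch, seed, n_regions):
    """Macro condensed-history electron transport over the CT density grid.

    Decay voxels are sampled proportional to TIA; on introduction into a
    spongiosa voxel the electron's energy is apportioned through the EAF
    table (initial-emission class at birth, boundary-crossing otherwise) and
    the escape fraction continues across the voxel.  Returns
    (edep, rm_batch, book): per-voxel deposited energy (MeV), per-batch
    per-region RM energy, and per-batch (emitted, deposited, escaped).
    """
    np.random.seed(seed)
    nx, ny, nz = density.shape
    lx, ly, lz = nx * sx, ny * sy, nz * sz
    step_cap = 0.5 * min(sx, min(sy, sz))
    edep = np.zeros((nx, ny, nz))
    rm_batch = np.zeros((n_batch, n_regions))
    book = np.zeros((n_batch, 3))  # emitted, deposited, escaped
    eaf = np.empty(5)
    log_e = _LOG_E
    log_s = _LOG_S
    nvox = tia_cdf.size
    for h in range(n_hist):
        b = h % n_batch
        # decay site
        r = np.random.random()
        lo = 0
        hi = nvox - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if tia_cdf[mid] < r:
                lo = mid + 1
            else:
                hi = mid
        vi = lo
        i = vi // (ny * nz)
        j = (vi // nz) % ny
        k = vi % nz
        x = (i + np.random.random()) * sx
        y = (j + np.random.random()) * sy
        z = (k + np.random.random()) * sz
        # electron energy from the beta spectrum
        u = np.random.random()
        n_b = beta_cdf.size
        lo = 0
        hi = n_b - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if beta_cdf[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        i_b = max(lo, 1)
        w = ((u - beta_cdf[i_b - 1])
             / max(beta_cdf[i_b] - beta_cdf[i_b - 1], 1e-300))
        e = beta_e[i_b - 1] * (1.0 - w) + beta_e[i_b] * w
        book[b, 0] += e
        ux, uy, uz = _isotropic()
        born = True
        while True:
            i = int(x / sx)
            j = int(y / sy)
            k = int(z / sz)
            if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
                book[b, 2] += e
                break
            if e <= E_CUT_MEV:
                edep[i, j, k] += e
                book[b, 1] += e
                break
            if spong[i, j, k] == 1:
                cls = 0 if born else 1
                if has4 == 1 and tumor4[i, j, k] == 1:
                    eaf_interp(vals4, le4, ba4, ca4, e, bvf[i, j, k],
                               cf[i, j, k], cls, eaf)
                    esc = eaf[4]
                    rm_share = eaf[1]
                else:
                    eaf_interp(vals3, le3, ba3, ca3, e, bvf[i, j, k],
                               cf[i, j, k], cls, eaf)
                    esc = eaf[3]
                    rm_share = eaf[1]
                dep = e * (1.0 - esc)
                edep[i, j, k] += dep
                book[b, 1] += dep
                reg = region[i, j, k]
                if reg >= 0:
                    rm_batch[b, reg] += e * rm_share
                e *= esc
                born = False
                # fly across the voxel; residual energy continues outside
                t = _exit_distance(x, y, z, ux, uy, uz, i, j, k, sx, sy, sz)
                x += (t + 1e-6) * ux
                y += (t + 1e-6) * uy
                z += (t + 1e-6) * uz
                continue
            born = False
            rho = density[i, j, k]
            if rho < 1e-3:
                rho = 1e-3
            s_lin = _stop_water_nb(e, log_e, log_s) * rho / 10.0  # MeV/mm
            ds = FRAC_STEP * e / s_lin
            if ds > step_cap:
                ds = step_cap
            de = s_lin * ds
            if e - de <= E_CUT_MEV:
                edep[i, j, k] += e
                book[b, 1] += e
                break
            edep[i, j, k] += de
            book[b, 1] += de
            e -= de
            ux, uy, uz = _isotropic()
            x += ds * ux
            y += ds * uy
            z += ds * uz
    return edep, rm_batch, book


@njit(cache=False)
def photon_kernel(density, region, rm_massfrac, tia_cdf,
                  line_e, line_y, mu_rho, muen_rho,
                  sx, sy, sz, n_hist, n_batch, seed, n_regions):
    """First-interaction photon kernel: each sampled decay emits each gamma
    line with its yield; the photon is ray-marched through the attenuating
    density map and deposits E*(mu_en/mu) at its first interaction site (the
    scattered remainder is tallied as escape)."""
    np.random.seed(seed)
    nx, ny, nz = density.shape
    edep = np.zeros((nx, ny, nz))
    rm_batch = np.zeros((n_batch, n_regions))
    book = np.zeros((n_batch, 3))
    nvox = tia_cdf.size
    nline = line_e.size
    for h in range(n_hist):
        b = h % n_batch
        r = np.random.random()
        lo = 0
        hi = nvox - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if tia_cdf[mid] < r:
                lo = mid + 1
            else:
                hi = mid
        vi = lo
        i0 = vi // (ny * nz)
        j0 = (vi // nz) % ny
        k0 = vi % nz
        for l in range(nline):
            if np.random.random() >= line_y[l]:
                continue
            e = line_e[l]
            book[b, 0] += e
            x = (i0 + np.random.random()) * sx
            y = (j0 + np.random.random()) * sy
            z = (k0 + np.random.random()) * sz
            ux, uy, uz = _isotropic()
            tau_target = -np.log(np.random.random())
            tau = 0.0
            while True:
                i = int(x / sx)
                j = int(y / sy)
                k = int(z / sz)
                if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
                    book[b, 2] += e
                    break
                rho = max(density[i, j, k], 1e-3)
                mu_lin = mu_rho[l] * rho / 10.0  # 1/mm
                t_exit = _exit_distance(x, y, z, ux, uy, uz, i, j, k,
                                        sx, sy, sz) + 1e-6
                if tau + mu_lin * t_exit >= tau_target:
                    dep = e * muen_rho[l] / mu_rho[l]
                    edep[i, j, k] += dep
                    book[b, 1] += dep
                    book[b, 2] += e - dep
                    reg = region[i, j, k]
                    if reg >= 0:
                        rm_batch[b, reg] += dep * rm_massfrac[i, j, k]
                    break
                tau += mu_lin * t_exit
                x += t_exit * ux
                y += t_exit * uy
                z += t_exit * uz
    return edep, rm_batch, book


# convenience: material arrays as contiguous float64 for the kernels
MAT_RHO = np.ascontiguousarray(MATERIAL_DENSITY)
MAT_SPR = np.ascontiguousarray(MATERIAL_S_RATIO)
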