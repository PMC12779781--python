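"""Voxel time-activity-curve fitting, AIC model selection, and analytic TIA.

Each voxel's serial activity concentrations are fitted with two candidate
models,

    mono:   A0 * exp(-lam * t)
    biexp3: A * (exp(-lam1 * t) - exp(-lam2 * t)),  lam2 > lam1,

and the fit with the lower Akaike information criterion is kept.  The AIC
uses the least-squares form AIC = n*ln(RSS/n) + 2k with the small-sample
correction (AICc) applied by default — voxel fits have 3-5 samples, far
inside the regime where the uncorrected AIC systematically over-selects the
larger model (the uncorrected form is a config switch).  A model is
eligible only when n >= k + 1, so with exactly three timepoints only the
monoexponential competes.  Time-integrated activity is
obtained by analytic integration of the winning model (A0/lam, or
A*(1/lam1 - 1/lam2)).

Numerical details: the RSS entering the AIC is floored at
n*(1e-8 * max activity)^2 so that on effectively noise-free data the
comparison degenerates gracefully to a parameter-count comparison instead of
amplifying floating-point dust; decay constants are bounded to
[1e-9, 1] 1/s; optimizer starts come from a terminal log-linear fit with
three seeded restarts on non-convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from . import decay as _decay
from .volume_io import RegionMask, VoxelVolume

log = logging.getLogger(__name__)

LAMBDA_BOUNDS = (1e-9, 1.0)  # 1/s


@dataclass
class KineticsConfig:
    use_aicc: bool = True
    rss_floor_rel: float = 1e-8
    floor_physical_lambda: bool = False  # force lam >= 177Lu physical lambda
    n_restarts: int = 3


@dataclass
class TacFit:
    """One voxel's selected fit.  ``params``: (A0, lam) for mono,
    (A, lam1, lam2) for biexp3 with lam2 > lam1."""

    model: str  # 'mono' | 'biexp3'
    params: tuple
    aic: float
    rss: float
    degenerate: bool = False


@dataclass
class BloodFit:
    """Four-parameter biexponential blood curve A1*e^-l1t + A2*e^-l2t."""

    params: tuple  # (A1, lam1, A2, lam2)

    @property
    def integral(self) -> float:
        a1, l1, a2, l2 = self.params
        return a1 / l1 + a2 / l2

    def __call__(self, t):
        a1, l1, a2, l2 = self.params
        t = np.asarray(t, dtype=float)
        return a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t)


@dataclass
class TiaMap:
    """Per-voxel time-integrated activity (MBq·s) with fit provenance.

    ``model_choice``: 0 outside mask, 1 mono, 2 biexp3, 3 degenerate."""

    tia: VoxelVolume
    model_choice: np.ndarray

    def total(self, mask: RegionMask | None = None) -> float:
        data = np.asarray(self.tia.data)
        if mask is None:
            return float(data.sum())
        return float(data[mask.as_bool()].sum())


def _mono(t, a0, lam):
    return a0 * np.exp(-lam * t)


def _biexp3(t, a, lam1, dlam):
    lam2 = lam1 + dlam
    return a * (np.exp(-lam1 * t) - np.exp(-lam2 * t))


def _aic(n, k, rss, floor, use_aicc):
    rss = max(rss, floor)
    aic = n * np.log(rss / n) + 2 * k
    if use_aicc:
        # guarded denominator keeps the k = n - 1 case finite but heavily
        # penalized instead of excluding it outright
        aic += 2.0 * k * (k + 1) / max(n - k - 1, 0.5)
    return aic


def _fit_model(func, times, acts, p0, bounds, restarts, rng):
    """curve_fit with seeded restarts on poor convergence.

    The initial guess is accepted outright when its residual reaches the
    effective noise floor; otherwise up to ``restarts`` jittered starts are
    tried and the best residual kept."""
    best = None
    good_rss = times.size * (1e-6 * float(np.max(acts))) ** 2
    trials = [p0]
    lo, hi = bounds
    for _ in range(restarts):
        jitter = [p * float(rng.uniform(0.3, 3.0)) for p in p0]
        trials.append([min(max(v, lo_i * 1.01 if lo_i > 0 else v), 1e12)
                       for v, lo_i in zip(jitter, lo)])
    for trial in trials:
        try:
            with warnings.catch_warnings():
                # singular covariance on exact fits is expected and unused
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(func, times, acts, p0=trial,
                                    bounds=bounds, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((func(times, *popt) - acts) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        if best[1] <= good_rss:
            break
    return best


def fit_voxel_tac(times, activities,
                  config: KineticsConfig = KineticsConfig()) -> TacFit:
    """Fit one voxel TAC (times in s, activities in kBq/mL) and select by AIC."""
    times = np.asarray(times, dtype=float)
    acts = np.asarray(activities, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(acts < 0):
        raise ValueError("activities must be >= 0")
    n = times.size
    if np.all(acts == 0):
        return TacFit("mono", (0.0, 1e-5), aic=-np.inf, rss=0.0, degenerate=True)

    rng = np.random.default_rng(12345)
    floor = n * (config.rss_floor_rel * float(acts.max())) ** 2
    lam_lo = _decay.LAMBDA_PHYS if config.floor_physical_lambda else LAMBDA_BOUNDS[0]

    # terminal log-linear seed for the decay constant
    pos = acts > 0
    if pos.sum() >= 2:
        t2, a2 = times[pos][-2:], acts[pos][-2:]
        lam0 = (np.log(a2[0]) - np.log(a2[1])) / (t2[1] - t2[0])
    else:
        lam0 = 1e-5
    lam0 = float(np.clip(lam0, lam_lo * 1.01, LAMBDA_BOUNDS[1] * 0.5))

    candidates = []
    mono = _fit_model(_mono, times, acts,
                      [float(acts.max()), lam0],
                      ([0.0, lam_lo], [np.inf, LAMBDA_BOUNDS[1]]),
                      config.n_restarts, rng)
    if mono is not None:
        aic = _aic(n, 2, mono[1], floor, config.use_aicc)
        candidates.append(TacFit("mono", (float(mono[0][0]), float(mono[0][1])),
                                 aic, mono[1]))
    if n >= 4:  # biexp3 eligible only when n >= k+1 = 4
        bi = _fit_model(_biexp3, times, acts,
                        [float(acts.max()) * 2.0, lam0, 20.0 * lam0],
                        ([0.0, lam_lo, 1e-12],
                         [np.inf, LAMBDA_BOUNDS[1], LAMBDA_BOUNDS[1]]),
                        config.n_restarts, rng)
        if bi is not None:
            a, lam1, dlam = bi[0]
            aic = _aic(n, 3, bi[1], floor, config.use_aicc)
            candidates.append(TacFit("biexp3",
                                     (float(a), float(lam1), float(lam1 + dlam)),
                                     aic, bi[1]))
    if not candidates:
        raise RuntimeError("no TAC model converged")
    if len(candidates) == 1:
        return candidates[0]
    # lower AIC wins; exact tie -> fewer parameters (mono is listed first)
    return min(candidates, key=lambda f: (f.aic, len(f.params)))


def integrate_tac(fit: TacFit) -> float:
    """Analytic time integral of the fitted TAC (input-activity-units * s)."""
    if fit.degenerate:
        return 0.0
    if fit.model == "mono":
        a0, lam = fit.params
        if lam <= 0:
            raise ValueError("decay constant must be > 0")
        return a0 / lam
    a, lam1, lam2 = fit.params
    if lam1 <= 0 or lam2 <= 0:
        raise ValueError("decay constants must be > 0")
    if lam1 == lam2:
        log.warning("degenerate biexp3 (lam1 == lam2): curve vanishes, TIA 0")
        return 0.0
    return a * (1.0 / lam1 - 1.0 / lam2)


MODEL_CODE = {"none": 0, "mono": 1, "biexp3": 2, "degenerate": 3}


def build_tia_map(series, times, mask: RegionMask,
                  config: KineticsConfig = KineticsConfig()) -> TiaMap:
    """Voxel-wise fit + analytic integration inside ``mask``.

    ``series``: co-registered activity-concentration volumes (kBq/mL);
    ``times`` in seconds.  The returned TIA is per-voxel MBq·s.
    """
    first = series[0]
    for vol in series[1:]:
        first.require_same_grid(vol)
    if len(series) != len(times):
        raise ValueError("one volume per timepoint required")
    stack = np.stack([np.asarray(v.data, dtype=float) for v in series])
    times = np.asarray(times, dtype=float)
    sel = mask.as_bool()
    tia = np.zeros(first.shape)
    choice = np.zeros(first.shape, np.int8)
    v_ml = first.voxel_volume_ml
    unit_scale = 1e-3 if first.unit == "kBq/mL" else (1e-6 if first.unit == "Bq/mL" else None)
    if unit_scale is None:
        raise ValueError(f"unsupported activity unit {first.unit!r}")
    for i, j, k in zip(*np.nonzero(sel)):
        fit = fit_voxel_tac(times, stack[:, i, j, k], config)
        conc_integral = integrate_tac(fit)  # kBq·s/mL (or Bq·s/mL)
        tia[i, j, k] = max(conc_integral, 0.0) * v_ml * unit_scale
        choice[i, j, k] = MODEL_CODE["degenerate" if fit.degenerate else fit.model]
    vol = VoxelVolume(tia, first.spacing, "MBq·s", first.origin)
    return TiaMap(vol, choice)


def fit_blood_curve(times, aorta_mean_conc) -> BloodFit:
    """Four-parameter biexponential fit of the aorta blood curve.

    Requires >= 4 samples; with fewer the caller must fall back to a mono
    fit explicitly.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(aorta_mean_conc, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times.size < 4:
        raise ValueError("need >= 4 samples for a 4-parameter fit; "
                         "set a mono fallback explicitly if fewer")
    rng = np.random.default_rng(99)

    def biexp4(t, a1, dlam, a2, lam2):
        return a1 * np.exp(-(lam2 + dlam) * t) + a2 * np.exp(-lam2 * t)

    lam_slow = max((np.log(max(conc[-2], 1e-12)) - np.log(max(conc[-1], 1e-12)))
                   / (times[-1] - times[-2]), LAMBDA_BOUNDS[0] * 2)
    lam_slow = float(np.clip(lam_slow, 1e-9, 0.5))
    p0 = [float(conc.max()), 50.0 * lam_slow, max(float(conc[-1]), 1e-9), lam_slow]
    best = _fit_model(biexp4, times, conc, p0,
                      ([0.0, 1e-12, 0.0, LAMBDA_BOUNDS[0]],
                       [np.inf, 1.0, np.inf, LAMBDA_BOUNDS[1]]),
                      5, rng)
    if best is None:
        raise RuntimeError("blood biexponential fit did not converge")
    a1, dlam, a2, lam2 = best[0]
    return BloodFit((float(a1), float(lam2 + dlam), float(a2), float(lam2)))
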