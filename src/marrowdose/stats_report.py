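"""Dose-hematotoxicity statistics.

Relative percent change in blood counts, Spearman rank correlation with a
Bonferroni-adjusted significance level, and Lin's concordance correlation
coefficient (CCC) for between-method agreement.

Spearman P-values use an exhaustive permutation distribution for n <= 9
(the two-sided tail probability of |r| under all n! orderings, mid-ranks for
ties) and the t approximation above that.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

PERMUTATION_N_MAX = 9


def relative_change(baseline, followup):
    """Relative percent change 100*(followup - baseline)/baseline.

    Non-positive baselines are excluded (NaN) with a logged reason, per the
    blood-panel contract.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    bad = baseline <= 0
    if np.any(bad):
        log.warning("excluding %d value(s) with baseline <= 0 from relative "
                    "change", int(np.sum(bad)))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, 100.0 * (followup - baseline) / baseline)
    return float(out) if out.ndim == 0 else out


def _rank(v):
    return sps.rankdata(v)  # mid-ranks for ties


def _pearson(x, y):
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float((xc * yc).sum() / den) if den > 0 else np.nan


@dataclass
class SpearmanResult:
    r: float
    p: float
    adjusted_alpha: float
    significant: bool
    n: int
    method: str  # 'permutation' | 't-approx'


def spearman_bonferroni(dose, change, n_tests: int,
                        base_alpha: float = 0.05) -> SpearmanResult:
    """Spearman rank correlation with Bonferroni-adjusted significance.

    ``adjusted_alpha = base_alpha / n_tests``; significance is
    ``P <= adjusted_alpha``.
    """
    x = np.asarray(dose, dtype=float)
    y = np.asarray(change, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors required")
    if x.size < 4:
        raise ValueError("need >= 4 pairs")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing pairs must be dropped before calling")
    adjusted = base_alpha / n_tests
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant input: Spearman r undefined")
        return SpearmanResult(np.nan, np.nan, adjusted, False, x.size,
                              "undefined")
    rx = _rank(x)
    ry = _rank(y)
    r_obs = _pearson(rx, ry)
    n = x.size
    if n <= PERMUTATION_N_MAX:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        num = ryc @ rxc
        den = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
        r_all = num / den
        p = float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))
        method = "permutation"
    else:
        t = r_obs * np.sqrt((n - 2) / max(1.0 - r_obs ** 2, 1e-15))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
        method = "t-approx"
    return SpearmanResult(r_obs, p, adjusted, p <= adjusted, n, method)


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n)
    moments: 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("paired vectors of length >= 2 required")
    if np.all(x == x[0]) and np.all(y == y[0]):
        log.warning("constant vectors: CCC undefined")
        return np.nan
    sx = x.var()
    sy = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / (sx + sy + (x.mean() - y.mean()) ** 2))


# ---------------------------------------------------------------------------
# Blood-panel layer
# ---------------------------------------------------------------------------

def panel_changes(panel: pd.DataFrame, followup_weeks: float = 6.0,
                  exclude_subjects=()) -> pd.DataFrame:
    """Per-subject, per-marker relative percent change from baseline.

    ``panel`` columns: subject, marker, time_weeks, value.  Baseline is
    time 0; missing follow-ups or non-positive baselines are dropped with a
    logged reason; ``exclude_subjects`` is an explicit input flag.
    """
    rows = []
    for (subj, marker), grp in panel.groupby(["subject", "marker"]):
        if subj in exclude_subjects:
            log.info("subject %s excluded by input flag", subj)
            continue
        base = grp.loc[grp.time_weeks == 0.0, "value"]
        fut = grp.loc[np.isclose(grp.time_weeks, followup_weeks), "value"]
        if base.empty or fut.empty:
            log.info("subject %s marker %s: missing baseline/follow-up, "
                     "dropped", subj, marker)
            continue
        change = relative_change(float(base.iloc[0]), float(fut.iloc[0]))
        if np.isnan(change):
            continue
        rows.append((subj, marker, change))
    return pd.DataFrame(rows, columns=["subject", "marker", "pct_change"])


def correlation_grid(doses: dict, changes: pd.DataFrame,
                     base_alpha: float = 0.05) -> pd.DataFrame:
    """Spearman grid of method x marker (Bonferroni across markers).

    ``doses``: method -> {subject: dose Gy}.  Returns one row per
    (method, marker) with r, P, adjusted alpha and the significance flag.
    """
    markers = sorted(changes.marker.unique())
    rows = []
    for method, dose_map in doses.items():
        for marker in markers:
            sub = changes[changes.marker == marker]
            subjects = [s for s in sub.subject if s in dose_map]
            if len(subjects) < 4:
                continue
            d = [dose_map[s] for s in subjects]
            c = [float(sub.loc[sub.subject == s, "pct_change"].iloc[0])
                 for s in subjects]
            res = spearman_bonferroni(d, c, n_tests=len(markers),
                                      base_alpha=base_alpha)
            rows.append((method, marker, res.r, res.p, res.adjusted_alpha,
                         res.significant, res.n))
    return pd.DataFrame(rows, columns=["method", "marker", "r", "p",
                                       "adjusted_alpha", "significant", "n"])


def plot_correlation_grid(grid: pd.DataFrame, path):
    """Heat map of Spearman r (method x marker) with significance outlines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(dict.fromkeys(grid.method))
    markers = list(dict.fromkeys(grid.marker))
    mat = np.full((len(methods), len(markers)), np.nan)
    sig = np.zeros_like(mat, dtype=bool)
    for _, row in grid.iterrows():
        i, j = methods.index(row.method), markers.index(row.marker)
        mat[i, j] = row.r
        sig[i, j] = row.significant
    fig, ax = plt.subplots(figsize=(1.2 * len(markers) + 2, len(methods) + 1.5))
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
    for i in range(len(methods)):
        for j in range(len(markers)):
            if np.isfinite(mat[i, j]):
                ax.text(j, i, f"{mat[i, j]:.2f}", ha="center", va="center")
                if sig[i, j]:
                    ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1,
                                               fill=False, edgecolor="red",
                                               linewidth=2))
    ax.set_xticks(range(len(markers)), markers, rotation=30, ha="right")
    ax.set_yticks(range(len(methods)), methods)
    fig.colorbar(im, ax=ax, label="Spearman r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
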