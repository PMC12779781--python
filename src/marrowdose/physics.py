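"""Electron and photon interaction data used by the transport engines.

Electron collision mass stopping powers for liquid water are packaged as a
small log-log interpolation table (approximate values from standard
tabulations, adequate for the simplified condensed-history model used here).
Other tissues are handled through per-material mass-stopping-power ratios
relative to water and their mass densities.

Compartment material codes shared by the micro- and macro-scale engines:

====  ==============  ==============  ==========
code  material        density g/mL    S ratio
====  ==============  ==============  ==========
0     trabecular bone 1.92            0.95
1     red marrow      1.03            1.00
2     yellow marrow   0.98            1.01
3     tumor           1.00            1.00
====  ==============  ==============  ==========
"""

from __future__ import annotations

import numpy as np

# --- electron stopping power, liquid water, MeV cm^2/g (collision) ----------
STOPPING_E_KEV = np.array(
    [10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 70.0, 100.0, 150.0, 200.0,
     300.0, 400.0, 500.0, 700.0, 1000.0, 1500.0, 2000.0, 2500.0]
)
STOPPING_WATER = np.array(
    [22.56, 16.47, 13.17, 9.653, 7.781, 6.603, 5.281, 4.115, 3.238, 2.793,
     2.355, 2.148, 2.034, 1.921, 1.849, 1.822, 1.824, 1.834]
)

_LOG_E = np.log10(STOPPING_E_KEV)
_LOG_S = np.log10(STOPPING_WATER)

# bone, RM, YM, tumor
MATERIAL_DENSITY = np.array([1.92, 1.03, 0.98, 1.00])
MATERIAL_S_RATIO = np.array([0.95, 1.00, 1.01, 1.00])
MAT_BONE, MAT_RM, MAT_YM, MAT_TUMOR = 0, 1, 2, 3


def stopping_power_water(energy_kev):
    """Collision mass stopping power of water, MeV cm^2/g (log-log interp)."""
    e = np.clip(np.log10(np.asarray(energy_kev, dtype=float)), _LOG_E[0], _LOG_E[-1])
    return 10.0 ** np.interp(e, _LOG_E, _LOG_S)


def csda_range_mm(energy_kev: float, density_g_ml: float = 1.0) -> float:
    """Continuous-slowing-down range in mm, by numerical integration of 1/S.

    Integrated from a 1 keV cutoff up to ``energy_kev`` over a fine log grid.
    """
    e_hi = float(energy_kev)
    if e_hi <= 1.0:
        return 0.0
    grid = np.logspace(0.0, np.log10(e_hi), 400)  # keV
    s_lin = stopping_power_water(grid) * density_g_ml  # MeV/cm
    # dE in MeV; range in cm -> mm
    r_cm = np.trapezoid(1.0 / s_lin, grid * 1e-3)
    return 10.0 * r_cm


# --- photon attenuation, water, cm^2/g --------------------------------------
# (energy MeV, mu/rho, mu_en/rho) for the two principal 177Lu gamma lines
PHOTON_WATER = {
    0.1129: (0.165, 0.0259),
    0.2084: (0.136, 0.0297),
}

MEV_TO_J = 1.602176634e-13
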