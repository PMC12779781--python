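"""177Lu decay data for the dose engines.

The beta spectrum is built from the three principal beta branches with an
allowed spectrum shape and a simple non-relativistic Fermi (Coulomb)
correction, tabulated on an energy grid and sampled by inverse CDF.  The two
principal gamma lines are carried with their yields.  Discrete conversion and
Auger electrons are supported through ``electrons_discrete`` but are empty by
default; the engines use the mean electron energy computed from this same
object, so all energy-bookkeeping oracles are self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ME_C2_MEV = 0.51099895
ALPHA_FS = 1.0 / 137.036
_Z_DAUGHTER = 72  # Hf

# (endpoint keV, branch intensity) — principal 177Lu beta branches
BETA_BRANCHES = [(498.3, 0.794), (385.3, 0.090), (176.5, 0.122)]
# (energy MeV, yield per decay) — principal gamma lines
PHOTON_LINES = [(0.2084, 0.1038), (0.1129, 0.0620)]

HALF_LIFE_S = 6.647 * 86400.0
LAMBDA_PHYS = np.log(2.0) / HALF_LIFE_S  # 1/s


def _allowed_shape(e_mev: np.ndarray, q_mev: float) -> np.ndarray:
    """Allowed beta- spectrum shape with a simple Fermi factor."""
    w = e_mev / ME_C2_MEV + 1.0  # total energy, mc^2 units
    p = np.sqrt(np.maximum(w * w - 1.0, 0.0))
    shape = p * w * (q_mev - e_mev) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = 2.0 * np.pi * ALPHA_FS * _Z_DAUGHTER * w / np.maximum(p, 1e-12)
        fermi = eta / (1.0 - np.exp(-eta))
    out = np.where((e_mev > 0) & (e_mev < q_mev), shape * fermi, 0.0)
    return out


@dataclass
class DecayData:
    """Sampled emission data for one radionuclide.

    ``beta_energy_mev``/``beta_pdf`` tabulate the summed beta spectrum
    (pdf normalized to unit integral); ``beta_cdf`` is the sampling CDF.
    """

    beta_energy_mev: np.ndarray
    beta_pdf: np.ndarray
    beta_cdf: np.ndarray
    photons: list = field(default_factory=list)  # (energy MeV, yield)
    electrons_discrete: list = field(default_factory=list)  # (energy MeV, yield)

    def __post_init__(self):
        norm = np.trapezoid(self.beta_pdf, self.beta_energy_mev)
        if not np.isclose(norm, 1.0, rtol=1e-6):
            raise ValueError("beta spectrum pdf must integrate to 1")
        if any(y < 0 for _, y in self.photons + self.electrons_discrete):
            raise ValueError("emission yields must be >= 0")

    @property
    def mean_beta_energy_mev(self) -> float:
        return float(np.trapezoid(self.beta_energy_mev * self.beta_pdf,
                                  self.beta_energy_mev))

    @property
    def mean_electron_energy_mev(self) -> float:
        """Mean electron energy per decay (beta + discrete electrons)."""
        disc = sum(e * y for e, y in self.electrons_discrete)
        return self.mean_beta_energy_mev + disc

    @property
    def mean_photon_energy_mev(self) -> float:
        return sum(e * y for e, y in self.photons)

    def sample_beta(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Sample n beta energies (MeV) by inverse CDF."""
        u = rng.random(n)
        return np.interp(u, self.beta_cdf, self.beta_energy_mev)


def lu177_decay(n_grid: int = 512) -> DecayData:
    """Build the packaged 177Lu DecayData."""
    q_max = max(q for q, _ in BETA_BRANCHES) * 1e-3
    e = np.linspace(1e-4, q_max, n_grid)
    pdf = np.zeros_like(e)
    total = sum(i for _, i in BETA_BRANCHES)
    for q_kev, inten in BETA_BRANCHES:
        q = q_kev * 1e-3
        shape = _allowed_shape(e, q)
        area = np.trapezoid(shape, e)
        pdf += (inten / total) * shape / area
    pdf /= np.trapezoid(pdf, e)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(e))])
    cdf /= cdf[-1]
    return DecayData(beta_energy_mev=e, beta_pdf=pdf, beta_cdf=cdf,
                     photons=list(PHOTON_LINES))
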