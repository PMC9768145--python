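"""Packaged atomic constants for the elements occurring in bone tissue.

Atomic weights and anomalous scattering factors come from :mod:`gemmi`;
small tables that gemmi does not carry (K-shell binding energies, K-alpha
fluorescence lines, mean ionization potentials) are packaged here.  Only
the six elements of the bone composite (H, C, N, O, P, Ca) are supported;
any other symbol raises ``UnknownElementError``.
"""

from __future__ import annotations

import gemmi
import numpy as np

#: Elements with packaged constants.
ELEMENTS = ("H", "C", "N", "O", "P", "Ca")

#: K-shell (1s) electron binding energies in keV.
K_EDGE_KEV = {
    "H": 0.0136,
    "C": 0.2842,
    "N": 0.4099,
    "O": 0.5431,
    "P": 2.1455,
    "Ca": 4.0381,
}

#: K-alpha1 fluorescence line energies in keV (no K-alpha for hydrogen).
KALPHA_KEV = {
    "C": 0.2770,
    "N": 0.3924,
    "O": 0.5249,
    "P": 2.0137,
    "Ca": 3.6917,
}

#: Mean ionization potentials J in keV (ICRU-37 style values), used by the
#: Joy-Luo stopping-power formula.
MEAN_IONIZATION_KEV = {
    "H": 0.0192,
    "C": 0.0780,
    "N": 0.0820,
    "O": 0.0950,
    "P": 0.1730,
    "Ca": 0.1910,
}

#: Classical electron radius in cm.
R_E_CM = 2.8179403262e-13
#: Avogadro's number per mol.
N_AVOGADRO = 6.02214076e23
#: hc in keV * Angstrom.
HC_KEV_A = 12.398419843320026

#: Photon energy range (keV) over which attenuation constants are served.
ENERGY_RANGE_KEV = (1.0, 100.0)


class UnknownElementError(KeyError):
    """Raised for an element symbol without packaged constants."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"no packaged constants for element symbol {self.symbol!r}"


def _check_symbol(symbol: str) -> str:
    if symbol not in ELEMENTS:
        raise UnknownElementError(symbol)
    return symbol


def atomic_number(symbol: str) -> int:
    return gemmi.Element(_check_symbol(symbol)).atomic_number


def atomic_weight(symbol: str) -> float:
    """Standard atomic weight in g/mol."""
    return gemmi.Element(_check_symbol(symbol)).weight


def wavelength_angstrom(energy_kev: float) -> float:
    """Photon wavelength (A) from energy (keV)."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_A / energy_kev


def mu_rho_photoelectric(symbol: str, energy_kev: float) -> float:
    """Photoelectric mass attenuation coefficient (cm^2/g).

    Computed from the imaginary anomalous scattering factor f'' via the
    optical theorem, sigma_pe = 2 r_e lambda f''.  Coherent and Compton
    scattering are deliberately excluded; in mineralized tissue at the
    energies of interest the photoelectric channel dominates absorbed
    energy.
    """
    _check_symbol(symbol)
    lo, hi = ENERGY_RANGE_KEV
    if not (lo <= energy_kev <= hi):
        raise ValueError(
            f"photon energy {energy_kev} keV outside packaged range {lo}-{hi} keV"
        )
    z = atomic_number(symbol)
    _, fpp = gemmi.cromer_liberman(z=z, energy=energy_kev * 1000.0)
    sigma_cm2 = 2.0 * R_E_CM * wavelength_angstrom(energy_kev) * 1e-8 * fpp
    return sigma_cm2 * N_AVOGADRO / atomic_weight(symbol)


def mu_rho_photoelectric_many(symbols, energy_kev: float) -> np.ndarray:
    return np.array([mu_rho_photoelectric(s, energy_kev) for s in symbols])
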