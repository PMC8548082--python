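"""Electron-optical constants and a parameterized atomic potential.

The atomic electrostatic potential uses a screened-Coulomb (Wentzel) model
with the Thomas--Fermi screening radius ``R = 0.885 a0 Z^(-1/3)``, reduced
to a single Gaussian per element that matches the Wentzel atom's integrated
potential (``4 pi e_k Z R^2`` with ``e_k = e / 4 pi eps0 = 14.3996 V*A``)
and its projected mean-square radius (``<b^2> = 4 R^2``).  The coefficient
table is pluggable (`gaussian_coefficients`), so a higher-fidelity
multi-Gaussian fit can be substituted without touching the simulator; the
accuracy of the shipped single-Gaussian table relative to modern scattering
factor tabulations is a stated limitation of the package, acceptable at the
>= 1 A sampling used here.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Dict, Tuple

import numpy as np
import scipy.constants as const

__all__ = [
    "ELEMENT_Z",
    "electron_wavelength",
    "interaction_constant",
    "screening_radius",
    "gaussian_coefficients",
]

# Elements that appear in biological specimens (and common ions/ligands).
ELEMENT_Z: Dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "CO": 27,
    "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

_COULOMB_VA = 1e10 * const.e / (4.0 * math.pi * const.epsilon_0)  # 14.3996 V*A
_BOHR_A = 1e10 * const.value("Bohr radius")  # 0.5292 A


def electron_wavelength(energy_kev: float) -> float:
    """Relativistic de Broglie wavelength of an electron, in Angstrom.

    ``lambda = h c / sqrt(e U (2 m0 c^2 + e U))``; 300 keV -> 0.01969 A.
    """
    if energy_kev <= 0:
        raise ValueError(f"energy must be > 0 keV (got {energy_kev})")
    e_joule = energy_kev * 1e3 * const.e
    mc2 = const.m_e * const.c**2
    lam_m = const.h * const.c / math.sqrt(e_joule * (2.0 * mc2 + e_joule))
    return lam_m * 1e10


def interaction_constant(energy_kev: float) -> float:
    """Phase-object interaction constant sigma, in rad / (V * A).

    ``sigma = 2 pi m e lambda / h^2`` with the relativistic electron mass;
    at 300 keV this is 6.53e-4 rad/(V*A), giving the familiar ~0.32 rad
    phase shift through 100 A of vitreous ice (mean inner potential 4.87 V).
    """
    lam_m = electron_wavelength(energy_kev) * 1e-10
    gamma = 1.0 + energy_kev * 1e3 * const.e / (const.m_e * const.c**2)
    sigma_per_vm = 2.0 * math.pi * gamma * const.m_e * const.e * lam_m / const.h**2
    return sigma_per_vm * 1e-10  # 1/(V*m) -> 1/(V*A)


def screening_radius(z: int) -> float:
    """Thomas-Fermi screening radius in Angstrom."""
    return 0.885 * _BOHR_A * z ** (-1.0 / 3.0)


@lru_cache(maxsize=None)
def gaussian_coefficients(element: str) -> Tuple[float, float]:
    """Single-Gaussian atomic potential coefficients ``(A, c)`` for an element.

    The 3D potential is modelled as
    ``V(r) = A / ((2 pi)^(3/2) c^3) * exp(-r^2 / (2 c^2))`` (V), so the
    projection along any axis is
    ``Vp(b) = A / (2 pi c^2) * exp(-b^2 / (2 c^2))`` (V*A).

    ``A = 4 pi e_k Z R^2`` (V*A^3) equals the space integral of the Wentzel
    potential ``e_k Z exp(-r/R)/r``, and ``c = sqrt(2) R`` matches its
    projected mean-square radius.
    """
    key = element.strip().upper()
    if key not in ELEMENT_Z:
        raise KeyError(f"unknown element symbol: {element!r}")
    z = ELEMENT_Z[key]
    r_tf = screening_radius(z)
    amplitude = 4.0 * math.pi * _COULOMB_VA * z * r_tf**2
    return amplitude, math.sqrt(2.0) * r_tf


def element_amplitudes(elements: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized ``(A, c)`` lookup for an array of element symbols."""
    amps = np.empty(len(elements))
    widths = np.empty(len(elements))
    for i, el in enumerate(elements):
        amps[i], widths[i] = gaussian_coefficients(str(el))
    return amps, widths
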