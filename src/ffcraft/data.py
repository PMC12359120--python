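"""Element tables and physical constants.

Covalent radii are the Cordero et al. (2008) consensus values in Å
(single-bond, low-spin where applicable); van der Waals radii are the
Bondi (1964) set with the Rowland–Taylor value for H. Masses are
standard atomic weights in amu. Only elements relevant to organic and
common inorganic chemistry are tabulated; unknown symbols raise KeyError
at the call site with a clear message.
"""

from __future__ import annotations

import scipy.constants as _const

# kJ/mol per hartree
HARTREE_TO_KJMOL = _const.value("Hartree energy") * _const.Avogadro / 1000.0

# Boltzmann constant in kJ/mol/K (= molar gas constant / 1000)
KB_KJMOL = _const.R / 1000.0

# Coulomb constant e^2/(4 pi eps0) in kJ/mol * Å / e^2
COULOMB_KE = (
    _const.e**2 / (4.0 * _const.pi * _const.epsilon_0) * _const.Avogadro / 1000.0 * 1e10
)

COVALENT_RADII = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Zr": 1.75, "Mo": 1.54, "Ru": 1.46, "Rh": 1.42,
    "Pd": 1.39, "Ag": 1.45, "Cd": 1.44, "In": 1.42, "Sn": 1.39, "Sb": 1.39,
    "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "Pt": 1.36, "Au": 1.36, "Hg": 1.32, "Pb": 1.46,
}

VDW_RADII = {
    "H": 1.10, "He": 1.40,
    "Li": 1.81, "Be": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Zn": 1.39,
    "Ga": 1.87, "Ge": 2.11, "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "I": 1.98, "Xe": 2.16,
}

ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Fe": 55.845, "Zn": 65.38,
    "Br": 79.904, "I": 126.90,
}


def covalent_radius(symbol: str) -> float:
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element '{symbol}'") from None


def vdw_radius(symbol: str) -> float:
    try:
        return VDW_RADII[symbol]
    except KeyError:
        raise KeyError(f"no van der Waals radius tabulated for element '{symbol}'") from None


def atomic_mass(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element '{symbol}'") from None
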