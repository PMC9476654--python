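"""Physical constants and unit conversion.

Everything inside the package is expressed in Hartree atomic units:
energies in hartree, lengths in bohr, masses in electron masses (m_e),
time in atomic time units, and hbar = 1.  Conversions happen only at
I/O boundaries (XYZ files are in angstrom, reported tables in cm^-1).
"""

from __future__ import annotations

# CODATA-2018 conversion factors
HARTREE_TO_CM1 = 219_474.631_363_2
HARTREE_TO_KCALMOL = 627.509_474_063
HARTREE_TO_KJMOL = 2625.499_639_48
BOHR_TO_ANGSTROM = 0.529_177_210_903
AMU_TO_ME = 1822.888_486_209

#: conversion factor from each supported energy unit to hartree
_TO_HARTREE = {
    "hartree": 1.0,
    "cm-1": 1.0 / HARTREE_TO_CM1,
    "kcal/mol": 1.0 / HARTREE_TO_KCALMOL,
    "kJ/mol": 1.0 / HARTREE_TO_KJMOL,
}

ENERGY_UNITS = tuple(_TO_HARTREE)

# Isotope masses (amu).  The tables in this field quote isotopically pure
# masses; deuterium is its own symbol so isotopologues are plain label swaps.
ISOTOPE_MASSES_AMU = {
    "H": 1.007825,
    "D": 2.014102,
    "C": 12.0,
    "O": 15.994915,
    "N": 14.003074,
}


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy ``value`` between registry units.

    Supported units: ``hartree``, ``cm-1``, ``kcal/mol``, ``kJ/mol``.
    The conversion is exact linear scaling; round trips are identity to
    better than 1e-12 relative.
    """
    try:
        f = _TO_HARTREE[from_unit]
    except KeyError:
        raise ValueError(f"unknown energy unit {from_unit!r}; known: {ENERGY_UNITS}")
    try:
        t = _TO_HARTREE[to_unit]
    except KeyError:
        raise ValueError(f"unknown energy unit {to_unit!r}; known: {ENERGY_UNITS}")
    return value * (f / t)


def mass_amu_to_me(mass_amu: float) -> float:
    """Convert a mass in unified atomic mass units to electron masses."""
    return mass_amu * AMU_TO_ME


def atom_mass_me(symbol: str) -> float:
    """Mass of an isotope symbol in electron masses."""
    try:
        return ISOTOPE_MASSES_AMU[symbol] * AMU_TO_ME
    except KeyError:
        raise ValueError(
            f"no mass tabulated for element {symbol!r}; "
            f"known: {sorted(ISOTOPE_MASSES_AMU)}"
        )
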