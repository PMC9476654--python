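"""Geometry and energy/gradient record containers (atomic units)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import atom_mass_me


@dataclass
class Geometry:
    """A molecular geometry.

    Parameters
    ----------
    symbols : sequence of str
        Isotope symbols (e.g. ``H``, ``D``, ``C``, ``O``).
    coords : (N, 3) array
        Cartesian coordinates in bohr.
    masses : (N,) array, optional
        Per-atom masses in electron masses.  Defaults to the isotope table.
    """

    symbols: tuple[str, ...]
    coords: np.ndarray
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.symbols = tuple(self.symbols)
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.symbols), 3)
        if self.masses is None:
            self.masses = np.array([atom_mass_me(s) for s in self.symbols])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (len(self.symbols),):
            raise ValueError("masses must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")

    @property
    def natoms(self) -> int:
        return len(self.symbols)

    def flat(self) -> np.ndarray:
        """Coordinates as a flat length-3N vector (bohr)."""
        return self.coords.reshape(-1)

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(self.symbols, np.asarray(coords, float).reshape(self.natoms, 3),
                        self.masses.copy())

    def distances(self) -> np.ndarray:
        """All n(n-1)/2 internuclear distances, lexicographic pair order."""
        d = self.coords[:, None, :] - self.coords[None, :, :]
        r = np.sqrt((d * d).sum(-1))
        iu = np.triu_indices(self.natoms, 1)
        return r[iu]


@dataclass
class EnergyGradientRecord:
    """A geometry with its potential energy and optional Cartesian gradient.

    Energies in hartree, gradients in hartree/bohr.  ``provenance`` tags the
    origin of the energy: ``low-level``, ``high-level`` or ``correction``.
    """

    geometry: Geometry
    energy: float
    gradient: np.ndarray | None = None
    provenance: str = "low-level"

    def __post_init__(self) -> None:
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, float).reshape(-1)
            if self.gradient.size != 3 * self.geometry.natoms:
                raise ValueError("gradient length must be 3 * natoms")


def pair_index(natoms: int) -> list[tuple[int, int]]:
    """Canonical lexicographic ordering of atom pairs (i < j)."""
    return [(i, j) for i in range(natoms) for j in range(i + 1, natoms)]
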