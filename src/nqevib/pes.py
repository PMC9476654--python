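"""Potential evaluators and analytic reference potentials.

A :class:`PotentialEvaluator` maps flat coordinate vectors (length ``ndim``,
bohr) to energies (hartree), with optional analytic gradients and Hessians
(finite-difference fallbacks are provided).  For a molecule ``ndim = 3N`` and
``masses`` repeats each atom's mass over x, y, z; for reduced-dimensional
models each coordinate carries its own (effective) mass, so the same DMC and
semiclassical machinery runs on 1-D oscillators and full molecules alike.

Analytic fixtures:

* :class:`HarmonicND` — separable harmonic bath with exact ZPE ``sum(w)/2``.
* :class:`Morse1D` — Morse oscillator with closed-form levels
  ``E_n = we (n + 1/2) - wexe (n + 1/2)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import HARTREE_TO_CM1


class PotentialEvaluator:
    """Base class: energies, gradients and Hessians on flat coordinates."""

    ndim: int
    masses: np.ndarray  # per-coordinate masses, m_e

    def value(self, x: np.ndarray) -> np.ndarray:
        """Potential energy (hartree). ``x``: (..., ndim) -> (...)."""
        raise NotImplementedError

    def gradient(self, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
        """Gradient dV/dx (hartree/bohr); central difference by default."""
        x = np.asarray(x, float)
        g = np.empty_like(x)
        for i in range(self.ndim):
            e = np.zeros(self.ndim)
            e[i] = step
            g[..., i] = (self.value(x + e) - self.value(x - e)) / (2 * step)
        return g

    def hessian(self, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Symmetrized central-difference Hessian of shape (..., ndim, ndim)."""
        x = np.asarray(x, float)
        h = np.empty(x.shape[:-1] + (self.ndim, self.ndim))
        for i in range(self.ndim):
            e = np.zeros(self.ndim)
            e[i] = step
            h[..., i, :] = (self.gradient(x + e) - self.gradient(x - e)) / (2 * step)
        return 0.5 * (h + np.swapaxes(h, -1, -2))


class HarmonicND(PotentialEvaluator):
    """Separable harmonic potential ``V = sum_i m_i w_i^2 x_i^2 / 2``."""

    def __init__(self, omegas_cm1, masses_me):
        self.omegas = np.atleast_1d(np.asarray(omegas_cm1, float)) / HARTREE_TO_CM1
        if np.any(self.omegas <= 0):
            raise ValueError("all frequencies must be positive")
        self.masses = np.atleast_1d(np.asarray(masses_me, float))
        if self.masses.shape != self.omegas.shape:
            raise ValueError("need one mass per mode")
        self.ndim = self.omegas.size
        self._k = self.masses * self.omegas**2

    def value(self, x):
        x = np.asarray(x, float)
        return 0.5 * (self._k * x**2).sum(-1)

    def gradient(self, x, step=None):
        return self._k * np.asarray(x, float)

    def hessian(self, x, step=None):
        x = np.asarray(x, float)
        h = np.diag(self._k)
        return np.broadcast_to(h, x.shape[:-1] + (self.ndim, self.ndim)).copy()

    def zpe_cm1(self) -> float:
        """Exact zero-point energy, cm^-1."""
        return 0.5 * self.omegas.sum() * HARTREE_TO_CM1


def harmonic_nd(frequencies_cm1, masses_me) -> HarmonicND:
    """Harmonic potential with the given normal-mode frequencies (cm^-1)."""
    return HarmonicND(frequencies_cm1, masses_me)


@dataclass
class Morse1D(PotentialEvaluator):
    """1-D Morse oscillator ``V(r) = De (1 - exp(-a (r - re)))^2``.

    Parameters in atomic units: ``de`` hartree, ``a`` 1/bohr, ``mass`` m_e,
    ``re`` bohr.
    """

    de: float
    a: float
    mass: float
    re: float = 0.0

    def __post_init__(self):
        if self.de <= 0 or self.a <= 0 or self.mass <= 0:
            raise ValueError("de, a and mass must be positive")
        self.ndim = 1
        self.masses = np.array([self.mass])

    def value(self, x):
        x = np.asarray(x, float)
        y = 1.0 - np.exp(-self.a * (x[..., 0] - self.re))
        return self.de * y * y

    def gradient(self, x, step=None):
        x = np.asarray(x, float)
        e = np.exp(-self.a * (x[..., 0] - self.re))
        return (2.0 * self.de * self.a * e * (1.0 - e))[..., None]

    @property
    def we(self) -> float:
        """Harmonic frequency (hartree)."""
        return self.a * np.sqrt(2.0 * self.de / self.mass)

    @property
    def wexe(self) -> float:
        """Anharmonicity constant (hartree)."""
        return self.a**2 / (2.0 * self.mass)

    def nlevels(self) -> int:
        """Number of bound levels, floor(1/(2 xe) - 1/2) + 1."""
        xe = self.wexe / self.we
        return int(np.floor(1.0 / (2.0 * xe) - 0.5)) + 1

    def levels_cm1(self) -> np.ndarray:
        """All bound levels E_n relative to the potential minimum, cm^-1."""
        n = np.arange(self.nlevels()) + 0.5
        return (self.we * n - self.wexe * n**2) * HARTREE_TO_CM1

    def zpe_cm1(self) -> float:
        return float(self.levels_cm1()[0])


def morse_levels(morse: Morse1D) -> np.ndarray:
    """Analytic bound-state energies of a Morse oscillator (cm^-1)."""
    return morse.levels_cm1()


class SumPotential(PotentialEvaluator):
    """Pointwise sum of evaluators sharing a coordinate convention."""

    def __init__(self, *parts: PotentialEvaluator):
        if not parts:
            raise ValueError("need at least one part")
        self.parts = parts
        self.ndim = parts[0].ndim
        self.masses = parts[0].masses
        for p in parts[1:]:
            if p.ndim != self.ndim:
                raise ValueError("all parts must share ndim")

    def value(self, x):
        return sum(p.value(x) for p in self.parts)

    def gradient(self, x, step=1e-5):
        return sum(p.gradient(x) for p in self.parts)
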