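"""Shared fixtures: synthetic molecules, analytic oscillators, fitted models."""

from __future__ import annotations

import numpy as np
import pytest

from nqevib.datasets import ethanol_torsion_constraints
from nqevib.pes import HarmonicND, Morse1D, PotentialEvaluator
from nqevib.synthetic import make_model_molecule, sample_corpus
from nqevib.torsion import fit_torsion2d
from nqevib.units import AMU_TO_ME, HARTREE_TO_CM1


@pytest.fixture(scope="session")
def molecule():
    """Deterministic 9-atom synthetic molecule with 321111 symmetry."""
    return make_model_molecule("321111", seed=7)


@pytest.fixture(scope="session")
def small_corpus(molecule):
    """A 400-record corpus below 35 000 cm^-1 (seeded)."""
    return sample_corpus(molecule, 400, 35_000.0, seed=3)


@pytest.fixture(scope="session")
def torsion_model():
    """The 2-D torsional model constrained to the printed cut energies."""
    return fit_torsion2d(ethanol_torsion_constraints())


@pytest.fixture(scope="session")
def morse_500():
    """Morse oscillator with we = 500, wexe = 10 cm^-1 (E0 = 247.5)."""
    we = 500.0 / HARTREE_TO_CM1
    wexe = 10.0 / HARTREE_TO_CM1
    mass = 1.0 * AMU_TO_ME
    return Morse1D(de=we**2 / (4 * wexe), a=np.sqrt(2 * mass * wexe),
                   mass=mass)


@pytest.fixture
def harmonic_500():
    """1-D harmonic oscillator at 500 cm^-1 with a 1 amu mass."""
    return HarmonicND([500.0], [AMU_TO_ME])


class CoupledQuartic(PotentialEvaluator):
    """Two harmonic modes with a strong q1^2 q2^2 coupling (chaotic)."""

    def __init__(self, omegas_cm1, coupling, mass_me=AMU_TO_ME):
        self.omegas = np.asarray(omegas_cm1, float) / HARTREE_TO_CM1
        self.coupling = coupling
        self.ndim = 2
        self.masses = np.full(2, mass_me)
        self._k = self.masses * self.omegas**2

    def value(self, x):
        x = np.asarray(x, float)
        q1, q2 = x[..., 0], x[..., 1]
        return (0.5 * (self._k[0] * q1**2 + self._k[1] * q2**2)
                + self.coupling * q1**2 * q2**2)

    def gradient(self, x, step=None):
        x = np.asarray(x, float)
        q1, q2 = x[..., 0], x[..., 1]
        g = np.empty_like(x)
        g[..., 0] = self._k[0] * q1 + 2 * self.coupling * q1 * q2**2
        g[..., 1] = self._k[1] * q2 + 2 * self.coupling * q2 * q1**2
        return g


@pytest.fixture
def chaotic_pes():
    return CoupledQuartic([900.0, 1300.0], coupling=0.05)
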