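"""Finite-difference Hessians and mass-weighted normal-mode analysis.

Frequencies are reported in cm^-1 with imaginary frequencies encoded as
negative numbers (a first-order saddle shows exactly one negative entry).
Translations and rotations are projected out by diagonalizing the
mass-weighted Hessian in the orthogonal complement of the translation /
rotation subspace; linear molecules (rank-5 subspace) are handled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry
from .pes import PotentialEvaluator
from .units import HARTREE_TO_CM1


@dataclass
class HessianFD:
    """Symmetrized central-difference Hessian with its asymmetry diagnostic."""

    matrix: np.ndarray
    asymmetry: float   # max |H - H^T| before symmetrization, hartree/bohr^2
    step: float


def _hessian_raw(pes, x, step):
    n = x.size
    h = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        h[i] = (pes.gradient(x + e) - pes.gradient(x - e)) / (2 * step)
    return h


def hessian_fd(pes: PotentialEvaluator, x: np.ndarray | Geometry,
               step: float = 1e-3, richardson: bool = False) -> HessianFD:
    """Central-difference Hessian of ``pes`` at ``x`` (flat bohr vector).

    With ``richardson=True`` the step-halved extrapolant ``(4 H(h/2) - H(h))/3``
    removes the leading O(h^2) truncation error (worth it when near-zero
    eigenvalues such as projected rotations must come out clean).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if isinstance(x, Geometry):
        x = x.flat()
    x = np.asarray(x, float)
    h = _hessian_raw(pes, x, step)
    if richardson:
        h = (4.0 * _hessian_raw(pes, x, step / 2) - h) / 3.0
    asym = float(np.abs(h - h.T).max())
    return HessianFD(0.5 * (h + h.T), asym, step)


@dataclass
class NormalModeSet:
    """Projected normal modes at a reference geometry.

    ``freqs_cm1`` are sorted ascending (negative = imaginary); ``modes`` has
    one orthonormal mass-weighted column per retained vibration;
    ``trrot_freqs_cm1`` are the projected-out frequencies (near zero at a
    true stationary point).
    """

    freqs_cm1: np.ndarray
    modes: np.ndarray
    geometry: Geometry | None
    trrot_freqs_cm1: np.ndarray

    @property
    def nmodes(self) -> int:
        return self.freqs_cm1.size

    def cartesian_modes(self, masses_per_dof: np.ndarray) -> np.ndarray:
        """Cartesian displacement vectors (columns), unnormalized."""
        return self.modes / np.sqrt(masses_per_dof)[:, None]


def _trrot_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (columns)."""
    n = coords.shape[0]
    sqm = np.sqrt(masses)
    com = (masses[:, None] * coords).sum(0) / masses.sum()
    rel = coords - com
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = sqm
        vecs.append(t.reshape(-1))
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        r = np.cross(rel, e) * sqm[:, None]
        vecs.append(r.reshape(-1))
    B = np.array(vecs).T
    # rank-revealing orthonormalization (a linear molecule loses one rotation)
    q, s, _ = np.linalg.svd(B, full_matrices=False)
    rank = int((s > 1e-8 * s[0]).sum())
    return q[:, :rank]


def analyze(hessian: np.ndarray | HessianFD, masses: np.ndarray,
            geom: Geometry | None = None) -> NormalModeSet:
    """Mass-weighted normal-mode analysis with translation/rotation projection.

    Parameters
    ----------
    hessian : (3N, 3N) Cartesian Hessian (hartree/bohr^2), or HessianFD
    masses : (N,) per-atom masses (m_e)
    geom : Geometry, optional
        Needed for the rotational projection; without it only translations
        are projected (useful for abstract coordinate models).
    """
    if isinstance(hessian, HessianFD):
        hessian = hessian.matrix
    masses = np.asarray(masses, float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    md = np.repeat(masses, 3)
    F = hessian / np.sqrt(np.outer(md, md))
    if geom is not None:
        T = _trrot_basis(geom.coords, masses)
    else:
        n = masses.size
        T = _trrot_basis(np.zeros((n, 3)), masses)[:, :3]
    # orthonormal basis of the vibrational complement
    proj = np.eye(F.shape[0]) - T @ T.T
    u, s, _ = np.linalg.svd(proj)
    ncomp = int((s > 0.5).sum())
    B = u[:, :ncomp]
    lam, vec = np.linalg.eigh(B.T @ F @ B)
    order = np.argsort(lam)
    lam, vec = lam[order], vec[:, order]
    freqs = np.sign(lam) * np.sqrt(np.abs(lam)) * HARTREE_TO_CM1
    modes = B @ vec
    lam_tr = np.linalg.eigvalsh(T.T @ F @ T)
    trrot = np.sign(lam_tr) * np.sqrt(np.abs(lam_tr)) * HARTREE_TO_CM1
    return NormalModeSet(freqs, modes, geom, trrot)


def normal_modes(pes: PotentialEvaluator, geom: Geometry,
                 step: float = 1e-3, richardson: bool = True) -> NormalModeSet:
    """Hessian + analysis in one call for a molecular potential."""
    h = hessian_fd(pes, geom, step, richardson=richardson)
    return analyze(h, geom.masses, geom)


def harmonic_zpe(freqs_cm1, electronic_offset_cm1: float = 0.0) -> float:
    """Harmonic zero-point energy: half the frequency sum plus an offset."""
    f = np.asarray(freqs_cm1, float)
    if np.any(f <= 0):
        raise ValueError("harmonic ZPE requires all-real (positive) frequencies")
    return 0.5 * float(f.sum()) + electronic_offset_cm1
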