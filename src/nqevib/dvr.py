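"""Periodic (azimuthal) discrete variable representation for hindered rotors.

The 1-D DVR lives on the uniform grid ``phi_j = 2 pi j / N`` (N odd) over
one full turn; the kinetic matrix has the closed form (B = hbar^2 / 2I)::

    T_jj  = B (N^2 - 1) / 12
    T_jj' = B (-1)^(j-j') cos(pi (j-j')/N) / (2 sin^2(pi (j-j')/N))

and the potential is diagonal on the grid, so a single dense
diagonalization yields the hindered-rotor levels.  The 2-D variant is the
direct product of two such grids with a diagonal potential surface; with
the torsional model's theta-phi cross terms removed it becomes the
separable comparison calculation.

Potentials are callables returning cm^-1; all levels are reported in cm^-1
relative to the lowest level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .torsion import TorsionModel2D
from .units import AMU_TO_ME, HARTREE_TO_CM1


def rotor_inertia_estimate(mu_amu: float, r_bohr: float) -> float:
    """Moment-of-inertia estimate ``mu r^2`` in amu*bohr^2."""
    if mu_amu <= 0 or r_bohr <= 0:
        raise ValueError("reduced mass and bond length must be positive")
    return mu_amu * r_bohr**2


@dataclass
class RotorSpec:
    """A rigid internal rotor described by its moment of inertia.

    ``inertia`` is stored in m_e*bohr^2; :meth:`from_amu` accepts the
    conventional amu*bohr^2 value (the printed "value/(N_AV m_e)" unit).
    """

    inertia: float

    def __post_init__(self):
        if self.inertia <= 0:
            raise ValueError("moment of inertia must be positive")

    @classmethod
    def from_amu(cls, inertia_amu_bohr2: float) -> "RotorSpec":
        return cls(inertia_amu_bohr2 * AMU_TO_ME)

    @property
    def rotational_constant_cm1(self) -> float:
        """B = hbar^2/(2I), cm^-1."""
        return HARTREE_TO_CM1 / (2.0 * self.inertia)


def _kinetic_periodic(n: int, b_cm1: float) -> np.ndarray:
    if n % 2 == 0:
        raise ValueError("the periodic DVR grid size must be odd")
    j = np.arange(n)
    diff = j[:, None] - j[None, :]
    T = np.empty((n, n))
    off = diff != 0
    d = diff[off]
    T[off] = ((-1.0) ** d) * np.cos(np.pi * d / n) / (2.0 * np.sin(np.pi * d / n) ** 2)
    T[~off] = (n * n - 1) / 12.0
    return b_cm1 * T


@dataclass
class DVRLevelSet:
    """Eigenvalues (cm^-1, relative to the lowest) and grid eigenvectors."""

    levels: np.ndarray           # relative to the lowest level
    ground_energy: float         # absolute energy of the lowest level, cm^-1
    vectors: np.ndarray          # (npoints, nlevels), grid-normalized
    grid: np.ndarray             # phi grid (radians); 2-D: (grid_phi, grid_theta)
    grid2: np.ndarray | None = None
    labels: list = field(default_factory=list)

    @property
    def npoints(self) -> int:
        return self.vectors.shape[0]

    def wavefunction(self, i: int) -> np.ndarray:
        return self.vectors[:, i]


def periodic_dvr_1d(potential, rotor: RotorSpec | float, n: int = 161,
                    nlevels: int | None = None) -> DVRLevelSet:
    """Hindered-rotor levels of a 2-pi-periodic 1-D potential (cm^-1).

    ``rotor`` may be a :class:`RotorSpec` or a plain inertia in m_e*bohr^2.
    ``n`` must be odd.
    """
    if not isinstance(rotor, RotorSpec):
        rotor = RotorSpec(float(rotor))
    grid = 2.0 * np.pi * np.arange(n) / n
    H = _kinetic_periodic(n, rotor.rotational_constant_cm1)
    v = np.asarray(potential(grid), float)
    H[np.diag_indices(n)] += v
    w, U = np.linalg.eigh(H)
    if nlevels is not None:
        w, U = w[:nlevels], U[:, :nlevels]
    return DVRLevelSet(w - w[0], float(w[0]), U, grid)


@dataclass
class OHTorsionResult:
    """1-D hydroxyl-torsion levels with the ground-state leak diagnostic."""

    levels: DVRLevelSet
    gauche_amplitude_ratio: float   # |psi_0(+-120 deg)| / max |psi_0|

    def wavefunctions(self) -> np.ndarray:
        return self.levels.vectors[:, :2]


def dvr_1d_oh_torsion(model: TorsionModel2D, rotor_oh: RotorSpec | float,
                      n: int = 161, theta_fixed: float = 0.0) -> OHTorsionResult:
    """Levels/wavefunctions of the hydroxyl cut at a fixed methyl angle.

    The leak diagnostic is the relative ground-state amplitude at the gauche
    angles (+-120 deg): delocalization of the torsional ground state over
    the trans and gauche wells.
    """
    cut = model.cut_oh(theta_fixed)
    ls = periodic_dvr_1d(cut, rotor_oh, n=n)
    psi0 = np.abs(ls.vectors[:, 0])
    targets = np.deg2rad([120.0, 240.0])
    amp = max(
        np.interp(t, ls.grid, psi0, period=2 * np.pi) for t in targets)
    return OHTorsionResult(ls, float(amp / psi0.max()))


def _nodal_count(profile: np.ndarray, threshold: float = 0.1) -> int:
    """Sign changes of a grid profile, ignoring amplitudes below threshold."""
    p = profile / np.abs(profile).max()
    sig = p[np.abs(p) > threshold]
    return int((np.sign(sig[1:]) != np.sign(sig[:-1])).sum())


def dvr_2d(model: TorsionModel2D, rotor_oh: RotorSpec | float,
           rotor_ch3: RotorSpec | float, n_phi: int = 81, n_theta: int = 41,
           omit_cross_terms: bool = False, nlevels: int = 16,
           size_cap: int = 6000) -> DVRLevelSet:
    """Direct-product 2-D DVR of the coupled torsional model.

    ``omit_cross_terms=True`` removes every theta-phi coupling term, which
    makes the potential separable (the comparison column).  Levels are
    relative to the lowest; labels carry (v_phi, v_theta, parity) with quantum numbers by
    nodal counting and parity from the (theta, phi) -> (-theta, -phi)
    reflection character.
    """
    if not isinstance(rotor_oh, RotorSpec):
        rotor_oh = RotorSpec(float(rotor_oh))
    if not isinstance(rotor_ch3, RotorSpec):
        rotor_ch3 = RotorSpec(float(rotor_ch3))
    if n_phi % 2 == 0 or n_theta % 2 == 0:
        raise ValueError("grid sizes must be odd")
    if n_phi * n_theta > size_cap:
        raise ValueError(
            f"grid {n_phi} x {n_theta} exceeds the size cap {size_cap}")
    m = model.without_cross_terms() if omit_cross_terms else model
    gp = 2.0 * np.pi * np.arange(n_phi) / n_phi
    gt = 2.0 * np.pi * np.arange(n_theta) / n_theta
    Tp = _kinetic_periodic(n_phi, rotor_oh.rotational_constant_cm1)
    Tt = _kinetic_periodic(n_theta, rotor_ch3.rotational_constant_cm1)
    V = m(gt[None, :], gp[:, None])                  # (n_phi, n_theta)
    npts = n_phi * n_theta
    if npts > 2000:
        # shift-invert Lanczos on the sparse direct-product Hamiltonian
        import scipy.sparse as sp
        from scipy.sparse.linalg import eigsh
        H = (sp.kron(sp.csr_matrix(Tp), sp.identity(n_theta))
             + sp.kron(sp.identity(n_phi), sp.csr_matrix(Tt))
             + sp.diags(V.reshape(-1)))
        w, U = eigsh(H.tocsc(), k=nlevels, sigma=float(V.min()) - 50.0)
        order = np.argsort(w)
        w, U = w[order], U[:, order]
    else:
        H = (np.kron(Tp, np.eye(n_theta)) + np.kron(np.eye(n_phi), Tt))
        H[np.diag_indices(npts)] += V.reshape(-1)
        w, U = np.linalg.eigh(H)
        w, U = w[:nlevels], U[:, :nlevels]

    labels = []
    # reflection (theta, phi) -> (-theta, -phi): grid index negation mod n
    ip = (-np.arange(n_phi)) % n_phi
    it = (-np.arange(n_theta)) % n_theta
    for i in range(len(w)):
        psi = U[:, i].reshape(n_phi, n_theta)
        jp = np.abs(psi).sum(axis=1).argmax()
        jt = np.abs(psi).sum(axis=0).argmax()
        v_phi = _nodal_count(psi[:, jt])
        v_theta = _nodal_count(psi[jp, :])
        refl = psi[np.ix_(ip, it)]
        char = float((psi * refl).sum())
        parity = "e" if char >= 0 else "o"
        labels.append((v_phi, v_theta, parity))
    return DVRLevelSet(w - w[0], float(w[0]), U, gp, gt, labels)
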