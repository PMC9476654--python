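"""Permutationally invariant polynomial (PIP) bases and surface fitting.

A PIP basis for an N-atom system is built over the n(n-1)/2 Morse variables
``x_ab = exp(-r_ab / lam)``.  Monomials in the Morse variables are grouped
into orbits under the permutation group of like atoms (the group acts on
atoms; its action on the pair variables is induced, never hand-coded), and
each basis function is the sum of the distinct monomials in one orbit.  The
potential is the linear expansion ``V(x) = sum_i c_i p_i(x)``, with the
coefficients obtained by (optionally gradient-augmented) linear least
squares.

The "delta" workflow corrects a smooth low-level surface with a low-order
PIP fit of the high-minus-low energy difference, referenced to the minimum
difference over the training set; the corrected surface is the pointwise sum
of the two fits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .geometry import Geometry, EnergyGradientRecord, pair_index
from .pes import PotentialEvaluator
from .units import HARTREE_TO_CM1


# ---------------------------------------------------------------------------
# Morse variables

def morse_variables(geom: Geometry, lam: float) -> np.ndarray:
    """Morse variables exp(-r_ab/lam) in canonical (lexicographic) pair order."""
    if lam <= 0:
        raise ValueError("the Morse range parameter lam must be positive")
    return np.exp(-geom.distances() / lam)


def _morse_batch(coords: np.ndarray, lam: float) -> np.ndarray:
    """Morse variables for a batch of flat coordinate vectors (..., 3N)."""
    c = coords.reshape(coords.shape[:-1] + (-1, 3))
    n = c.shape[-2]
    iu = np.triu_indices(n, 1)
    d = c[..., :, None, :] - c[..., None, :, :]
    r = np.sqrt((d * d).sum(-1))[..., iu[0], iu[1]]
    return np.exp(-r / lam)


# ---------------------------------------------------------------------------
# Permutation groups

def parse_signature(signature) -> tuple[int, ...]:
    """Normalize a permutation signature ('321111' or [3,2,1,...])."""
    if isinstance(signature, str):
        sig = tuple(int(ch) for ch in signature)
    else:
        sig = tuple(int(v) for v in signature)
    if not sig or any(v < 1 for v in sig):
        raise ValueError(f"invalid permutation signature {signature!r}")
    return sig


def atom_permutation_group(signature) -> list[tuple[int, ...]]:
    """All atom permutations exchanging atoms within each equivalence class."""
    sig = parse_signature(signature)
    blocks = []
    start = 0
    for size in sig:
        blocks.append(list(itertools.permutations(range(start, start + size))))
        start += size
    group = []
    for combo in itertools.product(*blocks):
        perm = tuple(itertools.chain.from_iterable(combo))
        group.append(perm)
    return group


def induced_pair_permutations(signature) -> list[np.ndarray]:
    """The action of the atom-permutation group on lexicographic atom pairs."""
    sig = parse_signature(signature)
    natoms = sum(sig)
    pairs = pair_index(natoms)
    pidx = {p: k for k, p in enumerate(pairs)}
    out = []
    for perm in atom_permutation_group(sig):
        mapped = np.array(
            [pidx[tuple(sorted((perm[i], perm[j])))] for (i, j) in pairs]
        )
        out.append(mapped)
    return out


# ---------------------------------------------------------------------------
# Basis generation: orbit enumeration over monomials

@dataclass
class PIPBasis:
    """Symmetry-adapted polynomial basis over Morse variables.

    ``orbits[i]`` is the list of distinct monomials (each a sorted tuple of
    variable indices, with repetition encoding the exponent) whose sum is the
    i-th basis function; the empty tuple is the constant function.
    """

    signature: tuple[int, ...]
    lam: float
    max_degree: int
    orbits: list[list[tuple[int, ...]]]
    _eval_cache: dict = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    @property
    def n_p(self) -> int:
        return len(self.orbits)

    @property
    def natoms(self) -> int:
        return sum(self.signature)

    @property
    def nvars(self) -> int:
        n = self.natoms
        return n * (n - 1) // 2

    # -- evaluation -------------------------------------------------------

    def _tables(self):
        """Per-degree monomial index arrays and the orbit scatter matrix."""
        if self._eval_cache is None:
            mons: list[tuple[int, ...]] = []
            orbit_of: list[int] = []
            for i, orb in enumerate(self.orbits):
                for m in orb:
                    mons.append(m)
                    orbit_of.append(i)
            by_deg: dict[int, list[int]] = {}
            for k, m in enumerate(mons):
                by_deg.setdefault(len(m), []).append(k)
            order = list(itertools.chain.from_iterable(by_deg.values()))
            deg_arrays = {
                d: np.array([mons[k] for k in idx], dtype=int).reshape(len(idx), d)
                for d, idx in by_deg.items()
            }
            scatter = sparse.csr_matrix(
                (np.ones(len(order)), ([orbit_of[k] for k in order],
                                       range(len(order)))),
                shape=(self.n_p, len(order)),
            )
            self._eval_cache = (by_deg, deg_arrays, scatter)
        return self._eval_cache

    def monomial_values(self, x: np.ndarray) -> np.ndarray:
        """Values of every monomial (in table order) for x of shape (m, nvars)."""
        by_deg, deg_arrays, _ = self._tables()
        cols = []
        for d in by_deg:
            A = deg_arrays[d]
            if d == 0:
                cols.append(np.ones((x.shape[0], A.shape[0])))
            else:
                cols.append(x[:, A].prod(axis=2))
        return np.concatenate(cols, axis=1)

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Basis values; ``x`` is (m, nvars) Morse variables -> (m, n_p)."""
        _, _, scatter = self._tables()
        return self.monomial_values(np.atleast_2d(x)) @ scatter.T

    def design_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(basis)/d(Morse variables): (m, nvars) -> (m, nvars, n_p)."""
        x = np.atleast_2d(x)
        by_deg, deg_arrays, scatter = self._tables()
        m = x.shape[0]
        cols = []
        for d in by_deg:
            A = deg_arrays[d]
            dmon = np.zeros((m, A.shape[0], self.nvars))
            if d > 0:
                vals = x[:, A]                      # (m, nmon, d)
                rows = np.arange(A.shape[0])
                for s in range(d):
                    # product over the other slots = d(monomial)/d(slot variable)
                    others = np.prod(np.delete(vals, s, axis=2), axis=2)
                    dmon[:, rows, A[:, s]] += others
            cols.append(dmon)
        dall = np.concatenate(cols, axis=1)          # (m, M, nvars)
        return np.einsum("pM,mMv->mvp", scatter.toarray(), dall)

    def evaluate(self, coeffs: np.ndarray, geom: Geometry) -> float:
        x = morse_variables(geom, self.lam)
        return float(self.design_matrix(x[None, :]) @ coeffs)


def generate_pip_basis(signature, max_degree: int, lam: float = 2.0) -> PIPBasis:
    """Enumerate monomial orbits of total degree <= ``max_degree``.

    Monomials are multisets of Morse-variable indices; the induced pair
    permutations act by relabelling, and one lexicographically minimal
    representative identifies each orbit.  The constant (empty multiset) is
    included, so ``n_p`` counts it.
    """
    if max_degree < 0:
        raise ValueError("max_degree must be >= 0")
    sig = parse_signature(signature)
    nvars = sum(sig) * (sum(sig) - 1) // 2
    group = [g.tolist() for g in induced_pair_permutations(sig)]
    seen: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    for d in range(max_degree + 1):
        for combo in itertools.combinations_with_replacement(range(nvars), d):
            images = {tuple(sorted(g[v] for v in combo)) for g in group}
            canon = min(images)
            if canon not in seen:
                seen[canon] = sorted(images)
    orbits = [seen[k] for k in sorted(seen, key=lambda t: (len(t), t))]
    return PIPBasis(sig, lam, max_degree, orbits)


# ---------------------------------------------------------------------------
# Fitting

class PIPPotential(PotentialEvaluator):
    """A fitted PIP expansion as a potential over flat Cartesian coordinates."""

    def __init__(self, basis: PIPBasis, coeffs: np.ndarray, template: Geometry,
                 shift: float = 0.0):
        self.basis = basis
        self.coeffs = np.asarray(coeffs, float)
        self.template = template
        self.shift = shift
        self.ndim = 3 * template.natoms
        self.masses = np.repeat(template.masses, 3)

    def value(self, x):
        x = np.asarray(x, float)
        flat = x.reshape(-1, self.ndim)
        mv = _morse_batch(flat, self.basis.lam)
        v = self.basis.design_matrix(mv) @ self.coeffs + self.shift
        return v.reshape(x.shape[:-1])

    def gradient(self, x, step=None):
        x = np.asarray(x, float)
        flat = x.reshape(-1, self.ndim)
        mv = _morse_batch(flat, self.basis.lam)
        dmorse = _morse_cartesian_jacobian(flat, self.basis.lam)  # (m, nvars, 3N)
        dbasis = self.basis.design_gradient(mv)                   # (m, nvars, n_p)
        g = np.einsum("mvp,p,mvc->mc", dbasis, self.coeffs, dmorse)
        return g.reshape(x.shape)


def _morse_cartesian_jacobian(flat: np.ndarray, lam: float) -> np.ndarray:
    """d x_ab / d(cartesian): (m, 3N) -> (m, nvars, 3N)."""
    m = flat.shape[0]
    c = flat.reshape(m, -1, 3)
    n = c.shape[1]
    pairs = pair_index(n)
    nvars = len(pairs)
    jac = np.zeros((m, nvars, n, 3))
    d = c[:, :, None, :] - c[:, None, :, :]
    r = np.sqrt((d * d).sum(-1))
    for v, (i, j) in enumerate(pairs):
        rij = r[:, i, j][:, None]
        unit = d[:, i, j, :] / rij
        x = np.exp(-rij / lam)
        jac[:, v, i, :] = -(x / lam) * unit
        jac[:, v, j, :] = (x / lam) * unit
    return jac.reshape(m, nvars, 3 * n)


@dataclass
class PIPFitResult:
    """Least-squares result for a PIP expansion.

    RMSEs are in cm^-1 (energies) and cm^-1/bohr (gradients); ``rank`` and
    ``condition`` are diagnostics of the normal system; ``rank_deficient``
    flags a minimum-norm solution.
    """

    basis: PIPBasis
    coeffs: np.ndarray
    rmse_energy_train: float
    rmse_gradient_train: float | None
    rank: int
    condition: float
    rank_deficient: bool
    rmse_energy_test: float | None = None
    rmse_gradient_test: float | None = None

    def potential(self, template: Geometry, shift: float = 0.0) -> PIPPotential:
        return PIPPotential(self.basis, self.coeffs, template, shift)

    def summary(self) -> str:
        lines = [
            "PIP least-squares fit",
            f"  basis functions     : {self.basis.n_p}"
            f"  (signature {''.join(map(str, self.basis.signature))},"
            f" degree {self.basis.max_degree}, lam {self.basis.lam} bohr)",
            f"  rank / condition    : {self.rank} / {self.condition:.3e}"
            + ("  [rank deficient -> minimum-norm]" if self.rank_deficient else ""),
            f"  train RMSE energy   : {self.rmse_energy_train:.4f} cm^-1",
        ]
        if self.rmse_gradient_train is not None:
            lines.append(
                f"  train RMSE gradient : {self.rmse_gradient_train:.4f} cm^-1/bohr")
        if self.rmse_energy_test is not None:
            lines.append(
                f"  test RMSE energy    : {self.rmse_energy_test:.4f} cm^-1")
        if self.rmse_gradient_test is not None:
            lines.append(
                f"  test RMSE gradient  : {self.rmse_gradient_test:.4f} cm^-1/bohr")
        return "\n".join(lines)


class PIPSurfaceModel:
    """Linear PIP model of a set of energy(/gradient) records.

    Parameters
    ----------
    basis : PIPBasis
    records : list of EnergyGradientRecord
    use_gradients : bool
        Append 3N gradient rows per record (analytic basis gradients via the
        chain rule).
    gradient_weight : float, optional
        Relative weight of each gradient row; defaults to 1/(3N).
    """

    def __init__(self, basis: PIPBasis, records: list[EnergyGradientRecord],
                 use_gradients: bool = False, gradient_weight: float | None = None):
        if not records:
            raise ValueError("no training records")
        self.basis = basis
        self.records = records
        self.use_gradients = use_gradients
        n3 = 3 * records[0].geometry.natoms
        self.gradient_weight = (
            gradient_weight if gradient_weight is not None else 1.0 / n3)

    def _rows(self, records, use_gradients):
        flat = np.array([r.geometry.flat() for r in records])
        mv = _morse_batch(flat, self.basis.lam)
        A = self.basis.design_matrix(mv)
        b = np.array([r.energy for r in records])
        if not use_gradients:
            return A, b, None, None
        dmorse = _morse_cartesian_jacobian(flat, self.basis.lam)
        dbasis = self.basis.design_gradient(mv)
        G = np.einsum("mvp,mvc->mcp", dbasis, dmorse)   # (m, 3N, n_p)
        g = np.array([
            r.gradient if r.gradient is not None else np.full(flat.shape[1], np.nan)
            for r in records
        ])
        if np.isnan(g).any():
            raise ValueError("use_gradients=True but some records lack gradients")
        return A, b, G.reshape(-1, self.basis.n_p), g.reshape(-1)

    def fit(self) -> PIPFitResult:
        A, b, G, g = self._rows(self.records, self.use_gradients)
        if self.use_gradients:
            w = self.gradient_weight
            M = np.vstack([A, w * G])
            y = np.concatenate([b, w * g])
        else:
            M, y = A, b
        coeffs, _, rank, sv = np.linalg.lstsq(M, y, rcond=None)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        res_e = A @ coeffs - b
        rmse_e = float(np.sqrt(np.mean(res_e**2))) * HARTREE_TO_CM1
        rmse_g = None
        if self.use_gradients:
            res_g = G @ coeffs - g
            rmse_g = float(np.sqrt(np.mean(res_g**2))) * HARTREE_TO_CM1
        return PIPFitResult(
            basis=self.basis, coeffs=coeffs,
            rmse_energy_train=rmse_e, rmse_gradient_train=rmse_g,
            rank=int(rank), condition=cond,
            rank_deficient=int(rank) < self.basis.n_p,
        )

    def score(self, result: PIPFitResult, records) -> PIPFitResult:
        """Fill in test RMSEs on held-out records (in place and returned)."""
        has_grad = all(r.gradient is not None for r in records)
        A, b, G, g = self._rows(records, has_grad)
        res = A @ result.coeffs - b
        result.rmse_energy_test = float(np.sqrt(np.mean(res**2))) * HARTREE_TO_CM1
        if has_grad:
            res_g = G @ result.coeffs - g
            result.rmse_gradient_test = (
                float(np.sqrt(np.mean(res_g**2))) * HARTREE_TO_CM1)
        return result


def fit_surface(basis: PIPBasis, train: list[EnergyGradientRecord],
                use_gradients: bool = False,
                gradient_weight: float | None = None) -> PIPFitResult:
    """Convenience wrapper: build a :class:`PIPSurfaceModel` and fit it."""
    return PIPSurfaceModel(basis, train, use_gradients, gradient_weight).fit()


# ---------------------------------------------------------------------------
# Delta correction and composition

@dataclass
class DeltaFit:
    """A fitted high-minus-low correction surface."""

    result: PIPFitResult
    reference_shift: float          # hartree subtracted from the raw difference
    template: Geometry

    @property
    def reference_shift_cm1(self) -> float:
        return self.reference_shift * HARTREE_TO_CM1

    def potential(self) -> PIPPotential:
        return self.result.potential(self.template)


def fit_delta(basis: PIPBasis, low: list[EnergyGradientRecord],
              high: list[EnergyGradientRecord]) -> DeltaFit:
    """Fit the correction surface on paired low/high energies.

    The target is ``E_high - E_low`` shifted so its minimum over the training
    set maps to zero (differences of absolute energies carry an arbitrary
    offset between the two electronic-structure references).
    """
    if len(low) != len(high):
        raise ValueError("low and high record lists must be paired")
    for lo, hi in zip(low, high):
        if not np.allclose(lo.geometry.coords, hi.geometry.coords):
            raise ValueError("paired records must share geometries")
    diff = np.array([hi.energy - lo.energy for lo, hi in zip(low, high)])
    shift = float(diff.min())
    target = [
        EnergyGradientRecord(lo.geometry, d - shift, None, "correction")
        for lo, d in zip(low, diff)
    ]
    result = PIPSurfaceModel(basis, target, use_gradients=False).fit()
    return DeltaFit(result, shift, low[0].geometry)


class ComposedSurface(PotentialEvaluator):
    """Corrected surface: pointwise sum of the low-level fit and the delta fit."""

    def __init__(self, v_ll: PotentialEvaluator, delta_v: PotentialEvaluator,
                 reference_shift_cm1: float = 0.0):
        if v_ll.ndim != delta_v.ndim:
            raise ValueError("evaluators must share the geometry convention")
        self.v_ll = v_ll
        self.delta_v = delta_v
        self.reference_shift_cm1 = reference_shift_cm1
        self.ndim = v_ll.ndim
        self.masses = v_ll.masses

    def value(self, x):
        return self.v_ll.value(x) + self.delta_v.value(x)

    def gradient(self, x, step=1e-5):
        return self.v_ll.gradient(x) + self.delta_v.gradient(x)


def compose_delta(v_ll: PotentialEvaluator, delta: PotentialEvaluator | DeltaFit
                  ) -> ComposedSurface:
    if isinstance(delta, DeltaFit):
        return ComposedSurface(v_ll, delta.potential(), delta.reference_shift_cm1)
    return ComposedSurface(v_ll, delta)
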