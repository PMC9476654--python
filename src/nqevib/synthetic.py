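"""Synthetic model molecules and training corpora.

The generator stands in for an ab initio database: a "high-level" potential
(a permutationally invariant sum of pairwise Morse bonds with class-pair
parameters), and a "low-level" potential equal to the high-level one plus a
smooth low-order PIP perturbation and a constant electronic offset.  The
high-minus-low difference is therefore (i) exactly representable in a
degree-2 PIP basis (planted-model recovery) and (ii) slowly varying — its
spread over a sampled corpus is a few percent of the high-level energy
range, which is the premise that makes a delta-correction with few
high-level points work.

Corpora are drawn by seeded random normal-mode displacements capped at a
target energy (default 35 000 cm^-1, the range the low-level surface is
meant to cover), and a deterministic selection recipe picks the sparse
subset that would be promoted to high-level single points: every eighth
record of the training pool, the first half of the test pool, and a handful
of high-energy add-ons from the remaining half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import EnergyGradientRecord, Geometry, pair_index
from .modes import NormalModeSet, normal_modes
from .pes import PotentialEvaluator
from .pip import PIPBasis, PIPPotential, generate_pip_basis, parse_signature
from .units import HARTREE_TO_CM1, atom_mass_me

_DEFAULT_CLASS_SYMBOLS = {3: "H", 2: "H", 1: "C"}


class PairMorsePotential(PotentialEvaluator):
    """Sum of Morse terms over every atom pair, parameters per class pair.

    Exactly invariant under permutations of same-class atoms because the
    (De, a, re) of a pair depend only on the unordered pair of classes.
    """

    def __init__(self, template: Geometry, pair_de, pair_a, pair_re):
        self.template = template
        self.ndim = 3 * template.natoms
        self.masses = np.repeat(template.masses, 3)
        self.de = np.asarray(pair_de, float)
        self.a = np.asarray(pair_a, float)
        self.re = np.asarray(pair_re, float)

    def _dist(self, x):
        c = np.asarray(x, float).reshape(-1, self.ndim // 3, 3)
        iu = np.triu_indices(c.shape[1], 1)
        d = c[:, :, None, :] - c[:, None, :, :]
        return np.sqrt((d * d).sum(-1))[:, iu[0], iu[1]], c, iu

    def value(self, x):
        x = np.asarray(x, float)
        r, _, _ = self._dist(x)
        y = 1.0 - np.exp(-self.a * (r - self.re))
        return (self.de * y * y).sum(-1).reshape(x.shape[:-1])

    def gradient(self, x, step=None):
        x = np.asarray(x, float)
        r, c, iu = self._dist(x)
        e = np.exp(-self.a * (r - self.re))
        dv = 2.0 * self.de * self.a * e * (1.0 - e)        # dV/dr per pair
        m, n = c.shape[0], c.shape[1]
        g = np.zeros((m, n, 3))
        diff = c[:, iu[0], :] - c[:, iu[1], :]
        unit = diff / r[..., None]
        contrib = dv[..., None] * unit
        np.add.at(g, (slice(None), iu[0]), contrib)
        np.add.at(g, (slice(None), iu[1]), -contrib)
        return g.reshape(x.shape)


@dataclass
class ModelMolecule:
    """A synthetic molecule with paired low/high-level potentials."""

    signature: tuple[int, ...]
    geometry: Geometry                  # equilibrium of the high-level surface
    high: PotentialEvaluator
    low: PotentialEvaluator
    modes: NormalModeSet
    e_min_high: float                   # hartree, V_high at equilibrium
    e_min_low: float
    perturbation_coeffs: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def natoms(self) -> int:
        return self.geometry.natoms


def _class_pair_params(sig, rng):
    """(De, a, re) per lexicographic atom pair, constant within class pairs."""
    natoms = sum(sig)
    cls = np.concatenate([[k] * s for k, s in enumerate(sig)])
    pairs = pair_index(natoms)
    keys = sorted({tuple(sorted((cls[i], cls[j]))) for i, j in pairs})
    de = {k: rng.uniform(0.08, 0.20) for k in keys}
    a = {k: rng.uniform(0.8, 1.2) for k in keys}
    re = {k: rng.uniform(2.2, 3.2) for k in keys}
    key_of = [tuple(sorted((cls[i], cls[j]))) for i, j in pairs]
    return (np.array([de[k] for k in key_of]),
            np.array([a[k] for k in key_of]),
            np.array([re[k] for k in key_of]))


def make_model_molecule(signature, seed: int,
                        symbols: list[str] | None = None,
                        perturbation_scale: float = 0.05,
                        offset_cm1: float = 35_732.0) -> ModelMolecule:
    """Build a seeded synthetic molecule with low/high potential pair.

    Parameters
    ----------
    signature : permutation signature, e.g. "321111" (class sizes).
    seed : RNG seed; identical seeds give bitwise-identical parameters.
    symbols : per-class element symbols; defaults to H for classes of
        identical hydrogens and C for singletons.
    perturbation_scale : target ratio of the low-minus-high perturbation
        range to the high-level sampling range (default 5%, emulating a
        correction of ~1800 over ~35 000 cm^-1).
    offset_cm1 : constant electronic offset between the two levels of
        theory; makes the raw high-minus-low difference large and nearly
        constant, so referencing it to its minimum matters.
    """
    sig = parse_signature(signature)
    natoms = sum(sig)
    if natoms < 3:
        raise ValueError("need at least 3 atoms")
    if symbols is None:
        symbols = [_DEFAULT_CLASS_SYMBOLS.get(s, "C") for s in sig]
    if len(symbols) != len(sig):
        raise ValueError("one symbol per signature class required")
    atom_symbols = [s for s, size in zip(symbols, sig) for _ in range(size)]

    rng = np.random.default_rng(seed)
    de, a, re = _class_pair_params(sig, rng)
    masses = np.array([atom_mass_me(s) for s in atom_symbols])

    # seeded start, then relax to the high-level equilibrium
    start = rng.uniform(-1.0, 1.0, (natoms, 3)) * 0.7 * np.mean(re)
    template = Geometry(atom_symbols, start, masses)
    high = PairMorsePotential(template, de, a, re)
    from scipy.optimize import minimize
    res = minimize(lambda q: high.value(q), start.reshape(-1),
                   jac=lambda q: high.gradient(q), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    q = res.x
    for _ in range(6):   # Newton polish so rotations project to < 0.1 cm^-1
        g = high.gradient(q)
        if np.abs(g).max() < 1e-13:
            break
        h = high.hessian(q, step=1e-4)
        q = q - np.linalg.lstsq(h, g, rcond=1e-10)[0]
    eq = Geometry(atom_symbols, q.reshape(natoms, 3), masses)
    high.template = eq
    modes = normal_modes(high, eq)
    if np.any(modes.freqs_cm1 <= 0):
        raise RuntimeError("high-level relaxation did not reach a minimum; "
                           "try another seed")

    # smooth degree-2 PIP perturbation, scaled on probe displacements
    basis = generate_pip_basis(sig, 2)
    raw = rng.standard_normal(basis.n_p)
    pert = PIPPotential(basis, raw, eq)
    probes = _displace(modes, eq, rng, 256, scale=1.0)
    v_high = high.value(probes)
    v_pert = pert.value(probes)
    span_h = np.ptp(v_high)
    span_p = np.ptp(v_pert)
    scale = perturbation_scale * span_h / span_p if span_p > 0 else 0.0
    coeffs = raw * scale
    offset = -offset_cm1 / HARTREE_TO_CM1
    pert = PIPPotential(basis, coeffs, eq, shift=offset)

    low = _LowLevel(high, pert)
    return ModelMolecule(sig, eq, high, low, modes,
                         e_min_high=float(high.value(eq.flat())),
                         e_min_low=float(low.value(eq.flat())),
                         perturbation_coeffs=coeffs)


class _LowLevel(PotentialEvaluator):
    """high-level + smooth perturbation = the emulated cheap surface."""

    def __init__(self, high, pert):
        self.high, self.pert = high, pert
        self.ndim = high.ndim
        self.masses = high.masses

    def value(self, x):
        return self.high.value(x) + self.pert.value(x)

    def gradient(self, x, step=None):
        return self.high.gradient(x) + self.pert.gradient(x)


def _displace(modes: NormalModeSet, eq: Geometry, rng, n: int,
              scale: float) -> np.ndarray:
    """Random normal-mode displacements; overall amplitude ~ U(0,1)*scale."""
    md = np.repeat(eq.masses, 3)
    omega = modes.freqs_cm1 / HARTREE_TO_CM1
    cart = modes.modes / np.sqrt(md)[:, None]          # cartesian mode vectors
    amp = rng.uniform(0.0, 1.0, (n, 1)) * scale
    z = rng.standard_normal((n, modes.nmodes))
    # per-mode sigma so each mode carries a comparable share of the cap
    sig = 1.0 / np.sqrt(omega * modes.nmodes)
    disp = (amp * z * sig) @ cart.T
    return eq.flat()[None, :] + disp


@dataclass
class Corpus:
    """Parallel low/high record lists over a shared geometry sample."""

    low: list[EnergyGradientRecord]
    high: list[EnergyGradientRecord]

    def __len__(self) -> int:
        return len(self.low)


def sample_corpus(mol: ModelMolecule, n: int, energy_cap_cm1: float,
                  seed: int, scale: float = 4.0) -> Corpus:
    """Draw ``n`` records below ``energy_cap_cm1`` (relative to the minimum).

    Displacements are independent normals along the high-level normal modes
    with a uniformly distributed overall amplitude, which fills the energy
    range from zero up to the cap; proposals above the cap are rejected.
    Aborts if the acceptance rate drops below 1%.
    """
    if n < 1 or energy_cap_cm1 <= 0:
        raise ValueError("need n >= 1 and a positive energy cap")
    rng = np.random.default_rng(seed)
    cap = energy_cap_cm1 / HARTREE_TO_CM1
    kept: list[np.ndarray] = []
    tried = 0
    if scale == 0.0:
        flat = np.tile(mol.geometry.flat(), (n, 1))
        kept = [flat]
    else:
        while sum(k.shape[0] for k in kept) < n:
            batch = max(n, 512)
            x = _displace(mol.modes, mol.geometry, rng, batch, scale)
            e = mol.high.value(x) - mol.e_min_high
            ok = e <= cap
            tried += batch
            kept.append(x[ok])
            got = sum(k.shape[0] for k in kept)
            if tried >= 100 * n and got < tried / 100:
                raise RuntimeError(
                    f"acceptance below 1% ({got}/{tried}); energy cap too low")
    X = np.concatenate(kept, axis=0)[:n]
    low_records, high_records = [], []
    for row in X:
        g = Geometry(mol.geometry.symbols, row.reshape(-1, 3),
                     mol.geometry.masses)
        low_records.append(EnergyGradientRecord(
            g, float(mol.low.value(row)), mol.low.gradient(row), "low-level"))
        high_records.append(EnergyGradientRecord(
            g, float(mol.high.value(row)), mol.high.gradient(row), "high-level"))
    return Corpus(low_records, high_records)


@dataclass
class SelectionPlan:
    """Sparse high-level selection recipe and final train/test partition."""

    train_pool: int = 8500
    test_pool: int = 2500
    stride: int = 8
    half_split: int = 1250
    addon_count: int = 6
    addon_threshold_cm1: float = 30_000.0
    final_train: int = 2069
    final_test: int = 250
    seed: int = 0

    def __post_init__(self):
        total = ((self.train_pool + self.stride - 1) // self.stride
                 + self.half_split + self.addon_count)
        if self.final_train + self.final_test != total:
            raise ValueError(
                f"final train+test ({self.final_train}+{self.final_test}) "
                f"must equal the selected total {total}")


@dataclass
class Selection:
    indices: list[int]          # indices into the concatenated pools
    train_ids: np.ndarray       # positions within `indices`
    test_ids: np.ndarray


def select_ccsdt_subset(train_pool: list[EnergyGradientRecord],
                        test_pool: list[EnergyGradientRecord],
                        plan: SelectionPlan) -> Selection:
    """Apply the every-eighth / half-split / high-energy-add-on recipe.

    Returns indices into ``train_pool + test_pool`` (training-pool records
    first), plus the seeded random partition into final train/test sets.
    """
    if len(train_pool) != plan.train_pool or len(test_pool) != plan.test_pool:
        raise ValueError("pool sizes do not match the plan")
    every_kth = list(range(0, plan.train_pool, plan.stride))   # 1-based 1, 9, ...
    first_half = [plan.train_pool + i for i in range(plan.half_split)]
    e = np.array([r.energy for r in test_pool])
    e_rel = (e - min(min(r.energy for r in train_pool), e.min())) * HARTREE_TO_CM1
    candidates = [i for i in range(plan.half_split, plan.test_pool)
                  if e_rel[i] > plan.addon_threshold_cm1]
    if len(candidates) < plan.addon_count:
        raise ValueError(
            f"only {len(candidates)} records above "
            f"{plan.addon_threshold_cm1} cm^-1 in the held-back half; "
            f"{plan.addon_count} required")
    addons = [plan.train_pool + i for i in candidates[:plan.addon_count]]
    indices = every_kth + first_half + addons
    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(indices))
    return Selection(indices, np.sort(order[:plan.final_train]),
                     np.sort(order[plan.final_train:]))
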