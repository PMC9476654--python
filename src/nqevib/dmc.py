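"""Unbiased diffusion Monte Carlo for vibrational zero-point energies.

Imaginary-time propagation of an ensemble of replicas ("walkers"): each
step every live walker takes a Gaussian diffusion step of standard
deviation ``sqrt(dtau / m)`` in each Cartesian degree of freedom, then is
compared with the reference energy ``E_r``:

* ``E_i > E_r``: the walker dies with probability ``1 - exp(-(E_i - E_r) dtau)``;
* ``E_i < E_r``: it spawns one copy with probability
  ``exp(-(E_r - E_i) dtau) - 1`` (capped at one birth per walker per step).

After branching the reference energy is updated with population feedback::

    E_r = <V> - alpha (N - N0) / N0

and the average of ``E_r`` over the post-equilibration steps estimates the
zero-point energy.  Repeating the simulation ``n_simulations`` times gives
the final ZPE as the mean and its statistical uncertainty as the standard
deviation of the per-simulation means.

Walkers whose potential falls below a floor under the global minimum have
entered an unphysical region of a fitted surface (a "hole"); they are
killed and counted, and the run continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pes import PotentialEvaluator
from .units import HARTREE_TO_CM1


@dataclass
class DMCConfig:
    """Run parameters for one set of DMC simulations.

    All times in atomic units; ``alpha`` defaults to ``1/dtau``.
    ``hole_floor_cm1`` is measured below the global minimum.
    """

    n_walkers: int = 1500
    dtau: float = 5.0
    n_steps: int = 6000
    n_equilibration: int = 2000
    alpha: float | None = None
    n_simulations: int = 5
    seed: int = 0
    hole_floor_cm1: float = 1000.0
    snapshot_stride: int | None = None   # None: final-step snapshot only

    def __post_init__(self):
        if self.n_steps <= self.n_equilibration:
            raise ValueError("n_steps must exceed n_equilibration")
        if self.dtau <= 0 or self.n_walkers < 1:
            raise ValueError("dtau must be positive and n_walkers >= 1")

    @property
    def feedback(self) -> float:
        return 1.0 / self.dtau if self.alpha is None else self.alpha


class ExtinctionError(RuntimeError):
    pass


def diffuse(positions: np.ndarray, masses_per_dof: np.ndarray, dtau: float,
            rng: np.random.Generator) -> np.ndarray:
    """One Gaussian diffusion step for every walker (rows)."""
    sigma = np.sqrt(dtau / masses_per_dof)
    return positions + rng.standard_normal(positions.shape) * sigma


def branch(positions: np.ndarray, energies: np.ndarray, e_ref: float,
           dtau: float, rng: np.random.Generator,
           hole_floor: float | None = None) -> tuple[np.ndarray, np.ndarray, int]:
    """Birth/death step.  Returns (positions, energies, hole_count).

    Deaths and single births from the exponential weight
    ``exp(-(E_i - E_r) dtau)``; walkers below ``hole_floor`` (absolute
    potential) are killed unconditionally and counted.
    """
    de = energies - e_ref
    u = rng.random(positions.shape[0])
    holes = 0
    if hole_floor is not None:
        in_hole = energies < hole_floor
        holes = int(in_hole.sum())
    else:
        in_hole = np.zeros(positions.shape[0], bool)
    p_death = np.where(de > 0, 1.0 - np.exp(-de * dtau), 0.0)
    survive = (u >= p_death) & ~in_hole
    p_birth = np.where(de < 0, np.minimum(np.exp(-de * dtau) - 1.0, 1.0), 0.0)
    born = (u < p_birth) & ~in_hole
    keep = positions[survive]
    keep_e = energies[survive]
    new = positions[born]
    new_e = energies[born]
    out = np.concatenate([keep, new], axis=0)
    out_e = np.concatenate([keep_e, new_e])
    if out.shape[0] == 0:
        raise ExtinctionError("all walkers died; reduce dtau or check the PES")
    return out, out_e, holes


def update_reference(energies: np.ndarray, alpha: float, n0: int) -> float:
    """Population-feedback reference energy ``<V> - alpha (N - N0)/N0``."""
    if energies.size == 0:
        raise ExtinctionError("no live walkers")
    return float(energies.mean()) - alpha * (energies.size - n0) / n0


@dataclass
class ZPEEstimate:
    """DMC zero-point energy with its per-simulation statistics (cm^-1)."""

    zpe_cm1: float
    sigma_cm1: float
    simulation_means_cm1: np.ndarray
    hole_count: int

    @staticmethod
    def sigma_from_means(means_cm1) -> float:
        """Statistical uncertainty: std of the simulation means."""
        m = np.asarray(means_cm1, float)
        return float(np.sqrt(np.mean((m - m.mean()) ** 2)))

    def summary(self) -> str:
        per = ", ".join(f"{v:.1f}" for v in self.simulation_means_cm1)
        return (
            f"DMC ZPE = {self.zpe_cm1:.1f} ({self.sigma_cm1:.1f}) cm^-1 over "
            f"{self.simulation_means_cm1.size} simulations\n"
            f"  per-simulation means: {per}\n"
            f"  holes encountered   : {self.hole_count}"
        )


@dataclass
class DMCResult:
    """Full output of :meth:`DMCSampler.run`."""

    estimate: ZPEEstimate
    reference_traces_cm1: list[np.ndarray]     # E_r - V_min per step, cm^-1
    snapshots: list[np.ndarray]                # live walker positions
    v_min: float                               # hartree, energy zero

    def summary(self) -> str:
        return self.estimate.summary()


class DMCSampler:
    """Unbiased DMC driver bound to a potential and a configuration.

    The potential's ``masses`` attribute supplies the per-degree-of-freedom
    masses; the walk starts from ``start`` (defaults to the coordinate
    origin of the potential's template if available, else zeros).
    """

    def __init__(self, pes: PotentialEvaluator, config: DMCConfig,
                 start: np.ndarray | None = None):
        self.pes = pes
        self.config = config
        if start is None:
            tmpl = getattr(pes, "template", None)
            start = tmpl.flat() if tmpl is not None else np.zeros(pes.ndim)
        self.start = np.asarray(start, float).reshape(-1)
        if self.start.size != pes.ndim:
            raise ValueError("start vector does not match the potential")

    def run(self, seed: int | None = None) -> DMCResult:
        cfg = self.config
        rng_master = np.random.default_rng(cfg.seed if seed is None else seed)
        v_min = float(self.pes.value(self.start))
        hole_floor = v_min - cfg.hole_floor_cm1 / HARTREE_TO_CM1
        masses = self.pes.masses
        traces, snapshots, means = [], [], []
        holes_total = 0
        for _ in range(cfg.n_simulations):
            rng = np.random.default_rng(rng_master.integers(2**63))
            pos = np.tile(self.start, (cfg.n_walkers, 1))
            e_ref = v_min
            trace = np.empty(cfg.n_steps)
            for step in range(cfg.n_steps):
                pos = diffuse(pos, masses, cfg.dtau, rng)
                energies = self.pes.value(pos)
                pos, energies, holes = branch(
                    pos, energies, e_ref, cfg.dtau, rng, hole_floor)
                holes_total += holes
                e_ref = update_reference(energies, cfg.feedback, cfg.n_walkers)
                trace[step] = e_ref
                if (cfg.snapshot_stride
                        and step % cfg.snapshot_stride == 0
                        and step >= cfg.n_equilibration):
                    snapshots.append(pos.copy())
            traces.append((trace - v_min) * HARTREE_TO_CM1)
            snapshots.append(pos.copy())
            means.append(traces[-1][cfg.n_equilibration:].mean())
        means = np.array(means)
        est = ZPEEstimate(
            zpe_cm1=float(means.mean()),
            sigma_cm1=ZPEEstimate.sigma_from_means(means),
            simulation_means_cm1=means,
            hole_count=holes_total,
        )
        return DMCResult(est, traces, snapshots, v_min)


def run_dmc(pes: PotentialEvaluator, config: DMCConfig,
            start: np.ndarray | None = None, seed: int | None = None) -> DMCResult:
    """Convenience wrapper around :class:`DMCSampler`."""
    return DMCSampler(pes, config, start).run(seed)


def walker_histogram(snapshots: list[np.ndarray], extractor, bins=101,
                     range=None) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of an internal coordinate over snapshot walkers.

    ``extractor`` maps an (n_walkers, ndim) position block to a 1-D array of
    the coordinate (e.g. a dihedral angle).  Returns (density, bin_edges).
    """
    if not snapshots:
        raise ValueError("no snapshots given")
    values = np.concatenate([np.asarray(extractor(s), float).reshape(-1)
                             for s in snapshots])
    dens, edges = np.histogram(values, bins=bins, range=range, density=True)
    return dens, edges
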