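"""Coupled two-rotor torsional potentials on a periodic Fourier form.

The model describes the joint hindered rotation of a 3-fold internal rotor
(methyl angle ``theta``) and a 1-fold rotor (hydroxyl angle ``phi``)::

    V(theta, phi) = sum_{j,k} c_jk cos(j phi) cos(3k theta)
                  + sum_{j,k} d_jk sin(j phi) sin(3k theta)

in cm^-1, with angles in radians.  The form builds in, exactly:

* 3-fold periodicity in ``theta`` (methyl symmetry),
* simultaneous reflection symmetry ``V(-theta, -phi) = V(theta, phi)``
  (the two gauche wells are an enantiomeric pair),
* 2-pi periodicity and realness.

The ``sin*sin`` block is the minimal coupling family that allows geared
motion (the methyl minimum drifting with the hydroxyl angle); the
separable, cross-term-free comparison model keeps only the terms that
depend on a single angle.

The fit is fully constrained: printed stationary energies and stationarity
conditions enter as exact linear constraints and the remaining coefficient
freedom is resolved by a smoothness-weighted minimum-norm solution (higher
Fourier orders are penalized), which is the smoothest surface consistent
with the data.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np


@dataclass
class TorsionModel2D:
    """Periodic Fourier surface in (theta, phi) with rotor inertias.

    ``c`` has shape (J+1, K+1) for the cos*cos block (c[0,0] is the additive
    constant); ``d`` has shape (J+1, K+1) with the j=0 row and k=0 column
    identically zero (sin*sin block).  Inertias are in m_e*bohr^2 and are
    carried for DVR use.
    """

    c: np.ndarray
    d: np.ndarray
    inertia_oh: float | None = None
    inertia_ch3: float | None = None

    def __post_init__(self):
        self.c = np.atleast_2d(np.asarray(self.c, float))
        self.d = np.atleast_2d(np.asarray(self.d, float))
        if self.d.shape != self.c.shape:
            raise ValueError("c and d blocks must share shape")
        if np.any(self.d[0, :] != 0) or np.any(self.d[:, 0] != 0):
            raise ValueError("sin*sin block must vanish for j=0 or k=0")

    @property
    def orders(self) -> tuple[int, int]:
        return self.c.shape[0] - 1, self.c.shape[1] - 1

    def _angles(self, theta, phi):
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        J, K = self.orders
        jj = np.arange(J + 1)
        kk = np.arange(K + 1)
        cj = np.cos(np.multiply.outer(phi, jj))
        sj = np.sin(np.multiply.outer(phi, jj))
        ck = np.cos(np.multiply.outer(3.0 * theta, kk))
        sk = np.sin(np.multiply.outer(3.0 * theta, kk))
        return cj, sj, ck, sk

    def __call__(self, theta, phi):
        """Potential (cm^-1) at angles in radians; broadcasts."""
        cj, sj, ck, sk = self._angles(theta, phi)
        return (np.einsum("...j,jk,...k->...", cj, self.c, ck)
                + np.einsum("...j,jk,...k->...", sj, self.d, sk))

    def dtheta(self, theta, phi):
        cj, sj, ck, sk = self._angles(theta, phi)
        kk = np.arange(self.orders[1] + 1)
        return (np.einsum("...j,jk,...k->...", cj, -3.0 * kk * self.c, sk)
                + np.einsum("...j,jk,...k->...", sj, 3.0 * kk * self.d, ck))

    def dphi(self, theta, phi):
        cj, sj, ck, sk = self._angles(theta, phi)
        jj = np.arange(self.orders[0] + 1)
        return (np.einsum("...j,jk,...k->...", sj, -(jj * self.c.T).T, ck)
                + np.einsum("...j,jk,...k->...", cj, (jj * self.d.T).T, sk))

    def without_cross_terms(self) -> "TorsionModel2D":
        """The separable comparison model: no theta-phi cross terms.

        Every product term with j > 0 and k > 0 couples the two angles, so
        the separable model keeps only the j = 0 column and k = 0 row of the
        cos*cos block (the sin*sin block is pure coupling and vanishes
        entirely): V(theta, phi) = f(phi) + g(theta).
        """
        c = np.zeros_like(self.c)
        c[0, :] = self.c[0, :]
        c[:, 0] = self.c[:, 0]
        c[0, 0] = self.c[0, 0]
        return TorsionModel2D(c, np.zeros_like(self.d),
                              self.inertia_oh, self.inertia_ch3)

    def cut_oh(self, theta_fixed: float = 0.0):
        """1-D hydroxyl-torsion cut V(phi) at fixed methyl angle (radians)."""
        return Cut1D(self, "phi", theta_fixed)

    def cut_methyl(self, phi_fixed: float = 0.0):
        """1-D methyl-torsion cut V(theta) at fixed hydroxyl angle."""
        return Cut1D(self, "theta", phi_fixed)

    def to_table(self):
        """Coefficient table rows (j, k, term, value_cm1) for serialization."""
        rows = []
        J, K = self.orders
        for j in range(J + 1):
            for k in range(K + 1):
                if self.c[j, k] != 0.0:
                    rows.append((j, k, "cos*cos", self.c[j, k]))
                if self.d[j, k] != 0.0:
                    rows.append((j, k, "sin*sin", self.d[j, k]))
        return rows


@dataclass
class Cut1D:
    """A periodic 1-D cut of a :class:`TorsionModel2D` (angles in radians)."""

    model: TorsionModel2D
    axis: str                   # which angle varies: "theta" or "phi"
    fixed_angle: float

    def __post_init__(self):
        if self.axis not in ("theta", "phi"):
            raise ValueError("axis must be 'theta' or 'phi'")

    @property
    def period(self) -> float:
        return 2.0 * np.pi

    def __call__(self, angle):
        if self.axis == "phi":
            return self.model(self.fixed_angle, angle)
        return self.model(angle, self.fixed_angle)

    def derivative(self, angle):
        if self.axis == "phi":
            return self.model.dphi(self.fixed_angle, angle)
        return self.model.dtheta(angle, self.fixed_angle)

    def barrier(self, n: int = 2048) -> float:
        """max - min over a fine grid of one full period."""
        a = np.linspace(0.0, self.period, n, endpoint=False)
        v = self(a)
        return float(v.max() - v.min())

    def grid_minimum(self, n: int = 2048) -> float:
        a = np.linspace(0.0, self.period, n, endpoint=False)
        return float(self(a).min())


def cut_1d(model: TorsionModel2D, which: str, fixed_angle: float) -> Cut1D:
    """Accessor by rotor name: ``which`` is 'oh' (phi varies) or 'ch3'/'methyl'."""
    if which.lower() in ("oh", "phi"):
        return model.cut_oh(fixed_angle)
    if which.lower() in ("ch3", "methyl", "theta"):
        return model.cut_methyl(fixed_angle)
    raise ValueError(f"unknown cut {which!r}")


# ---------------------------------------------------------------------------
# Constrained fitting

@dataclass
class TorsionConstraint:
    """One linear condition on the surface at a point (angles in degrees).

    kind: "value" (V = target), "dtheta" or "dphi" (derivative = target,
    usually 0 for stationarity).  Targets in cm^-1 (or cm^-1/rad).
    """

    kind: str
    theta_deg: float
    phi_deg: float
    target: float

    def __post_init__(self):
        if self.kind not in ("value", "dtheta", "dphi"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")


@dataclass
class CutConstraint:
    """Stationary points of one fixed-angle cut.

    ``points`` are (angle_deg, energy_cm1 or None, stationary_axes) where
    stationary_axes is a subset of {"theta", "phi"}; energy None constrains
    position only.
    """

    cut: str                     # "methyl" (theta varies) or "oh" (phi varies)
    fixed_angle_deg: float
    points: list[tuple[float, float | None, tuple[str, ...]]]

    def expand(self) -> list[TorsionConstraint]:
        rows = []
        for angle, value, axes in self.points:
            if self.cut == "methyl":
                th, ph = angle, self.fixed_angle_deg
            elif self.cut == "oh":
                th, ph = self.fixed_angle_deg, angle
            else:
                raise ValueError(f"unknown cut {self.cut!r}")
            if value is not None:
                if value < 0:
                    raise ValueError("target energies are relative to the "
                                     "global minimum and must be >= 0")
                rows.append(TorsionConstraint("value", th, ph, value))
            for ax in axes:
                rows.append(TorsionConstraint(f"d{ax}", th, ph, 0.0))
        return rows


class InfeasibleConstraints(ValueError):
    def __init__(self, max_residual, orders):
        self.max_residual = max_residual
        self.orders = orders
        super().__init__(
            f"constraint system infeasible at orders (J, K) = {orders}: "
            f"max residual {max_residual:.3g} cm^-1")


def _design_row(kind, theta, phi, J, K):
    jj = np.arange(J + 1)
    kk = np.arange(K + 1)
    cj, sj = np.cos(jj * phi), np.sin(jj * phi)
    ck, sk = np.cos(3 * kk * theta), np.sin(3 * kk * theta)
    if kind == "value":
        rc = np.outer(cj, ck)
        rd = np.outer(sj, sk)
    elif kind == "dtheta":
        rc = np.outer(cj, -3 * kk * sk)
        rd = np.outer(sj, 3 * kk * ck)
    else:  # dphi
        rc = np.outer(-jj * sj, ck)
        rd = np.outer(jj * cj, sk)
    return rc, rd


def fit_torsion2d(constraints, orders: tuple[int, int] = (6, 3),
                  inertia_oh: float | None = None,
                  inertia_ch3: float | None = None,
                  value_tol: float = 0.5, deriv_tol: float = 1e-6,
                  max_orders: tuple[int, int] = (12, 6)) -> TorsionModel2D:
    """Fit the Fourier surface to exact stationary-point constraints.

    ``constraints`` is a list of :class:`TorsionConstraint` or
    :class:`CutConstraint` (expanded automatically).  Orders are raised (one
    step in each direction at a time) until the linear system is solvable
    within ``value_tol`` cm^-1 and ``deriv_tol`` cm^-1/rad; leftover freedom
    is resolved by a smoothness-weighted minimum-norm solution.
    """
    rows: list[TorsionConstraint] = []
    for c in constraints:
        rows.extend(c.expand() if isinstance(c, CutConstraint) else [c])
    if not rows:
        raise ValueError("no constraints given")

    J, K = orders
    while True:
        A_c, A_d, b, kinds = [], [], [], []
        for r in rows:
            th, ph = np.deg2rad(r.theta_deg), np.deg2rad(r.phi_deg)
            rc, rd = _design_row(r.kind, th, ph, J, K)
            A_c.append(rc.reshape(-1))
            A_d.append(rd.reshape(-1))
            b.append(r.target)
            kinds.append(r.kind)
        # mask out identically-zero sin*sin entries (j=0 or k=0)
        dmask = np.ones((J + 1, K + 1), bool)
        dmask[0, :] = False
        dmask[:, 0] = False
        dmask = dmask.reshape(-1)
        A = np.hstack([np.array(A_c), np.array(A_d)[:, dmask]])
        b_arr = np.array(b)
        # smoothness weights: penalize high angular orders
        jj, kk = np.meshgrid(np.arange(J + 1), np.arange(K + 1), indexing="ij")
        w_full = 1.0 + jj**2 + (3 * kk) ** 2
        w = np.concatenate([w_full.reshape(-1), w_full.reshape(-1)[dmask]])
        z, *_ = np.linalg.lstsq(A / w, b_arr, rcond=None)
        coef = z / w
        resid = np.abs(A @ coef - b_arr)
        vt = np.array([k == "value" for k in kinds])
        ok = ((resid[vt] < value_tol).all() if vt.any() else True) and \
             ((resid[~vt] < deriv_tol).all() if (~vt).any() else True)
        if ok:
            nc = (J + 1) * (K + 1)
            c = coef[:nc].reshape(J + 1, K + 1)
            d = np.zeros((J + 1) * (K + 1))
            d[dmask] = coef[nc:]
            return TorsionModel2D(c, d.reshape(J + 1, K + 1),
                                  inertia_oh, inertia_ch3)
        if (J, K) >= max_orders:
            raise InfeasibleConstraints(float(resid.max()), (J, K))
        J = min(J + 1, max_orders[0])
        K = min(K + 1, max_orders[1])


# ---------------------------------------------------------------------------
# Minimum-energy path on the grid

@dataclass
class PathResult:
    """An axis-aligned grid path with its energy profile."""

    theta_deg: np.ndarray
    phi_deg: np.ndarray
    energy: np.ndarray
    segments: list[tuple[str, float]]    # ("theta"|"phi", signed extent in deg)

    @property
    def max_energy(self) -> float:
        return float(self.energy.max())


def _is_grid_minimum(E, i, j):
    nbrs = []
    if i > 0:
        nbrs.append(E[i - 1, j])
    if i < E.shape[0] - 1:
        nbrs.append(E[i + 1, j])
    if j > 0:
        nbrs.append(E[i, j - 1])
    if j < E.shape[1] - 1:
        nbrs.append(E[i, j + 1])
    return all(E[i, j] <= v for v in nbrs)


def minimum_energy_path(model: TorsionModel2D,
                        start_deg: tuple[float, float],
                        end_deg: tuple[float, float],
                        grid: float = 2.0) -> PathResult:
    """Lowest path between two wells, restricted to axis-aligned grid moves.

    Two-pass search: a bottleneck shortest path fixes the lowest attainable
    barrier B, then an ordinary shortest path on accumulated energy within
    the sublevel set {E <= B + eps} hugs the valley floor.  ``start`` and
    ``end`` are (theta, phi) in degrees and must be local minima; the domain
    is the unwrapped bounding box (so winding paths such as theta advancing
    a full turn are representable), padded by 90 degrees on each side.
    """
    pad = 90.0
    th_lo = min(start_deg[0], end_deg[0]) - pad
    th_hi = max(start_deg[0], end_deg[0]) + pad
    ph_lo = min(start_deg[1], end_deg[1]) - pad
    ph_hi = max(start_deg[1], end_deg[1]) + pad
    th = np.arange(th_lo, th_hi + grid / 2, grid)
    ph = np.arange(ph_lo, ph_hi + grid / 2, grid)
    E = model(np.deg2rad(th)[:, None], np.deg2rad(ph)[None, :])

    def node(p):
        i = int(round((p[0] - th_lo) / grid))
        j = int(round((p[1] - ph_lo) / grid))
        return i, j

    s, t = node(start_deg), node(end_deg)
    for name, (i, j) in (("start", s), ("end", t)):
        if not _is_grid_minimum(E, i, j):
            raise ValueError(f"{name} point is not a local minimum on the grid")

    # pass 1: bottleneck Dijkstra
    INF = np.inf
    best = np.full(E.shape, INF)
    best[s] = E[s]
    heap = [(E[s], s)]
    moves = ((1, 0), (-1, 0), (0, 1), (0, -1))
    while heap:
        bval, (i, j) = heapq.heappop(heap)
        if bval > best[i, j]:
            continue
        if (i, j) == t:
            break
        for di, dj in moves:
            ni, nj = i + di, j + dj
            if 0 <= ni < E.shape[0] and 0 <= nj < E.shape[1]:
                nb = max(bval, E[ni, nj])
                if nb < best[ni, nj]:
                    best[ni, nj] = nb
                    heapq.heappush(heap, (nb, (ni, nj)))
    barrier = best[t]

    # pass 2: accumulated-energy Dijkstra inside the sublevel set
    allowed = E <= barrier + 1e-9
    dist = np.full(E.shape, INF)
    prev = {}
    dist[s] = 0.0
    heap = [(0.0, s)]
    while heap:
        dval, (i, j) = heapq.heappop(heap)
        if dval > dist[i, j]:
            continue
        if (i, j) == t:
            break
        for di, dj in moves:
            ni, nj = i + di, j + dj
            if (0 <= ni < E.shape[0] and 0 <= nj < E.shape[1]
                    and allowed[ni, nj]):
                nd = dval + E[ni, nj] - E.min() + 1e-6
                if nd < dist[ni, nj]:
                    dist[ni, nj] = nd
                    prev[(ni, nj)] = (i, j)
                    heapq.heappush(heap, (nd, (ni, nj)))

    path = [t]
    while path[-1] != s:
        path.append(prev[path[-1]])
    path.reverse()
    pts = np.array(path)
    theta_deg = th_lo + pts[:, 0] * grid
    phi_deg = ph_lo + pts[:, 1] * grid
    energy = E[pts[:, 0], pts[:, 1]]

    segments: list[tuple[str, float]] = []
    for k in range(1, len(path)):
        di = theta_deg[k] - theta_deg[k - 1]
        dj = phi_deg[k] - phi_deg[k - 1]
        axis = "theta" if di != 0 else "phi"
        step = di if di != 0 else dj
        if segments and segments[-1][0] == axis and segments[-1][1] * step > 0:
            segments[-1] = (axis, segments[-1][1] + step)
        else:
            segments.append((axis, step))
    return PathResult(theta_deg, phi_deg, energy, segments)
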