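"""PIP basis generation, permutation invariance and surface fitting."""

import itertools

import numpy as np
import pytest

from nqevib.geometry import Geometry
from nqevib.pes import PotentialEvaluator
from nqevib.pip import (PIPPotential, PIPSurfaceModel, compose_delta,
                        fit_delta, generate_pip_basis,
                        induced_pair_permutations, morse_variables,
                        atom_permutation_group, parse_signature)
from nqevib.units import HARTREE_TO_CM1


# --------------------------------------------------------------------------
# independent Burnside oracle

def burnside_orbit_count(signature, max_degree):
    """Orbit count via Burnside's lemma: average number of fixed monomials."""
    group = induced_pair_permutations(signature)
    total = 0
    for perm in group:
        seen, cycles = set(), []
        for s in range(len(perm)):
            if s in seen:
                continue
            length, t = 0, s
            while t not in seen:
                seen.add(t)
                t = perm[t]
                length += 1
            cycles.append(length)
        dp = [0] * (max_degree + 1)
        dp[0] = 1
        for L in cycles:
            ndp = [0] * (max_degree + 1)
            for d in range(max_degree + 1):
                if dp[d]:
                    e = 0
                    while d + L * e <= max_degree:
                        ndp[d + L * e] += dp[d]
                        e += 1
            dp = ndp
        total += sum(dp)
    return total // len(group)


@pytest.mark.parametrize("signature,degree", [
    ("21", 3), ("211", 2), ("31", 3), ("221", 3), ("2211", 2), ("33", 2),
])
def test_orbit_count_matches_burnside(signature, degree):
    basis = generate_pip_basis(signature, degree)
    assert basis.n_p == burnside_orbit_count(signature, degree)


def test_two_distinct_atoms_degree_one():
    basis = generate_pip_basis("11", 1)
    assert basis.n_p == 2          # constant + x12


def test_morse_variable_definition():
    g = Geometry(["H", "H"], [[0, 0, 0], [0, 0, 2.0]])
    x = morse_variables(g, lam=2.0)
    assert x.shape == (1,)
    assert x[0] == pytest.approx(np.exp(-1.0), rel=1e-12)
    with pytest.raises(ValueError, match="positive"):
        morse_variables(g, lam=-1.0)


def test_nine_atoms_give_36_pair_variables(molecule):
    x = morse_variables(molecule.geometry, lam=2.0)
    assert x.size == 36
    assert np.all((x > 0) & (x <= 1))


def test_basis_invariant_under_class_permutations(molecule):
    """Basis values are unchanged by permutations of same-class atoms."""
    basis = generate_pip_basis("321111", 2)
    rng = np.random.default_rng(0)
    coords = molecule.geometry.coords + rng.normal(0, 0.3, (9, 3))
    x = morse_variables(molecule.geometry.with_coords(coords), 2.0)
    ref = basis.design_matrix(x[None, :])
    for perm in atom_permutation_group("321111")[1:]:
        pc = coords[list(perm)]
        xp = morse_variables(molecule.geometry.with_coords(pc), 2.0)
        val = basis.design_matrix(xp[None, :])
        assert np.allclose(val, ref, atol=1e-10)


def test_degree_zero_is_constant_only():
    assert generate_pip_basis("21", 0).n_p == 1
    with pytest.raises(ValueError):
        generate_pip_basis("21", -1)


def _random_records(molecule, n, seed, grad=False):
    from nqevib.synthetic import _displace
    rng = np.random.default_rng(seed)
    X = _displace(molecule.modes, molecule.geometry, rng, n, scale=2.0)
    out = []
    for row in X:
        g = Geometry(molecule.geometry.symbols, row.reshape(-1, 3),
                     molecule.geometry.masses)
        out.append(g)
    return X, out


def test_planted_coefficients_recovered(molecule):
    """Noiseless data generated on the basis are refit exactly."""
    basis = generate_pip_basis("321111", 2)
    rng = np.random.default_rng(5)
    true = rng.standard_normal(basis.n_p) * 1e-3
    planted = PIPPotential(basis, true, molecule.geometry)
    X, geoms = _random_records(molecule, 3 * basis.n_p, 11)
    from nqevib.geometry import EnergyGradientRecord
    records = [EnergyGradientRecord(g, float(planted.value(x)))
               for g, x in zip(geoms, X)]
    res = PIPSurfaceModel(basis, records).fit()
    assert res.rmse_energy_train < 1e-8        # cm^-1
    assert not res.rank_deficient
    assert np.allclose(res.coeffs, true, rtol=1e-6, atol=1e-12)


def test_underdetermined_fit_flagged(molecule):
    basis = generate_pip_basis("321111", 2)
    X, geoms = _random_records(molecule, 20, 13)
    from nqevib.geometry import EnergyGradientRecord
    records = [EnergyGradientRecord(g, float(molecule.high.value(x)))
               for g, x in zip(geoms, X)]
    res = PIPSurfaceModel(basis, records).fit()
    assert res.rank_deficient
    assert res.rmse_energy_train < 1e-6


def test_basis_gradients_match_finite_difference(molecule):
    basis = generate_pip_basis("321111", 2)
    rng = np.random.default_rng(2)
    coeffs = rng.standard_normal(basis.n_p)
    pot = PIPPotential(basis, coeffs, molecule.geometry)
    q = molecule.geometry.flat() + rng.normal(0, 0.1, 27)
    g = pot.gradient(q)
    gfd = PotentialEvaluator.gradient(pot, q)
    assert np.allclose(g, gfd, atol=1e-7)


def test_gradient_fit_improves_gradient_error(molecule, small_corpus):
    """Adding gradient rows lowers the held-out gradient RMSE."""
    basis = generate_pip_basis("321111", 2)
    train = small_corpus.low[:150]
    test = small_corpus.low[150:300]
    m_e = PIPSurfaceModel(basis, train, use_gradients=False)
    m_g = PIPSurfaceModel(basis, train, use_gradients=True)
    r_e = m_e.score(m_e.fit(), test)
    r_g = m_g.score(m_g.fit(), test)
    assert r_g.rmse_gradient_test < r_e.rmse_gradient_test


def test_delta_fit_recovers_planted_correction(molecule, small_corpus):
    """high - low is a degree-2 PIP by construction: exact recovery."""
    basis = generate_pip_basis("321111", 2)
    low, high = small_corpus.low[:300], small_corpus.high[:300]
    dfit = fit_delta(basis, low, high)
    assert dfit.result.rmse_energy_train < 1e-6
    # held-out geometries
    pot = dfit.potential()
    for lo, hi in zip(small_corpus.low[300:350], small_corpus.high[300:350]):
        pred = float(pot.value(lo.geometry.flat())) + dfit.reference_shift
        err = abs(pred - (hi.energy - lo.energy)) * HARTREE_TO_CM1
        assert err < 1e-6


def test_delta_fit_zero_when_levels_identical(molecule, small_corpus):
    basis = generate_pip_basis("321111", 2)
    low = small_corpus.low[:120]
    dfit = fit_delta(basis, low, low)
    pot = dfit.potential()
    vals = np.array([float(pot.value(r.geometry.flat())) for r in low[:20]])
    assert np.allclose(vals * HARTREE_TO_CM1, 0.0, atol=1e-8)
    assert dfit.reference_shift == 0.0


def test_correction_much_smaller_than_low_level_range(small_corpus):
    """The premise of the delta correction: a slowly varying difference."""
    e_low = np.array([r.energy for r in small_corpus.low])
    diff = np.array([h.energy - l.energy
                     for l, h in zip(small_corpus.low, small_corpus.high)])
    assert np.ptp(diff) < 0.10 * np.ptp(e_low)
    assert np.std(diff) < 0.10 * np.std(e_low)


def test_composed_surface_is_pointwise_sum(molecule, small_corpus):
    basis = generate_pip_basis("321111", 2)
    dfit = fit_delta(basis, small_corpus.low[:300], small_corpus.high[:300])
    composed = compose_delta(molecule.low, dfit)
    for r in small_corpus.low[:30]:
        q = r.geometry.flat()
        lhs = float(composed.value(q))
        rhs = float(molecule.low.value(q)) + float(dfit.potential().value(q))
        assert lhs == pytest.approx(rhs, abs=1e-12)
    # composed approximates the true high-level surface (planted model)
    for r in small_corpus.low[300:340]:
        q = r.geometry.flat()
        err = abs(float(composed.value(q)) + dfit.reference_shift
                  - float(molecule.high.value(q))) * HARTREE_TO_CM1
        assert err < 1e-6


def test_signature_parsing():
    assert parse_signature("321111") == (3, 2, 1, 1, 1, 1)
    assert parse_signature([2, 1]) == (2, 1)
    with pytest.raises(ValueError):
        parse_signature("0")
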