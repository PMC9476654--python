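"""Adiabatic switching and time-averaged Herman-Kluk spectral densities."""

import numpy as np
import pytest

from nqevib.ascivr import (ASConfig, ASSCIVRSampler, coherent_overlap,
                           harmonic_initial_conditions,
                           propagate_semiclassical, spectral_density,
                           switching_function)
from nqevib.pes import HarmonicND, Morse1D
from nqevib.units import AMU_TO_ME, HARTREE_TO_CM1


def test_switching_function_boundary_conditions():
    t_as = 25_000.0
    assert switching_function(0.0, t_as) == 0.0
    assert switching_function(t_as, t_as) == pytest.approx(1.0, abs=1e-14)
    eps = 1e-3
    for t0 in (0.0, t_as):
        rate = (switching_function(t0 + eps, t_as)
                - switching_function(max(t0 - eps, 0.0), t_as)) / eps
        assert abs(rate) < 1e-9


def test_initial_conditions_exactly_on_zpe_shell():
    w = np.array([500.0, 900.0]) / HARTREE_TO_CM1
    rng = np.random.default_rng(0)
    P, Q = harmonic_initial_conditions(w, 200, rng)
    e = 0.5 * (P**2).sum(1) + 0.5 * (w**2 * Q**2).sum(1)
    assert np.allclose(e, 0.5 * w.sum(), rtol=1e-12)


def test_phase_average_of_q_squared():
    w = np.array([800.0]) / HARTREE_TO_CM1
    rng = np.random.default_rng(1)
    _, Q = harmonic_initial_conditions(w, 10_000, rng)
    assert (Q[:, 0] ** 2).mean() == pytest.approx(1.0 / (2 * w[0]), rel=0.02)


def test_same_seed_reproduces_draws():
    w = np.array([500.0]) / HARTREE_TO_CM1
    a = harmonic_initial_conditions(w, 16, np.random.default_rng(5))
    b = harmonic_initial_conditions(w, 16, np.random.default_rng(5))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_imaginary_frequencies_rejected():
    with pytest.raises(ValueError, match="real frequencies"):
        harmonic_initial_conditions(np.array([-0.001]), 4,
                                    np.random.default_rng(0))


def test_coherent_overlap_identity_and_decay():
    g = np.array([0.002])
    one = coherent_overlap([0.1], [0.4], [0.1], [0.4], g)
    assert abs(one) == pytest.approx(1.0, rel=1e-14)
    # modulus decays with the stated Gaussian exponents
    val = coherent_overlap([0.0], [0.0], [0.0], [1.5], g)
    assert abs(val) == pytest.approx(np.exp(-g[0] * 1.5**2 / 4), rel=1e-12)
    val = coherent_overlap([0.0], [0.0], [0.05], [0.0], g)
    assert abs(val) == pytest.approx(np.exp(-0.05**2 / (4 * g[0])), rel=1e-12)


def test_coherent_overlap_matches_quadrature():
    """Closed form against direct numerical integration of the Gaussians."""
    g = np.array([0.01])
    p1, q1, p2, q2 = 0.3, 0.5, -0.1, -0.2
    x = np.linspace(-80, 80, 400_001)

    def state(p, q):
        return (g[0] / np.pi) ** 0.25 * np.exp(
            -g[0] * (x - q) ** 2 / 2 + 1j * p * (x - q))

    num = np.trapezoid(np.conj(state(p1, q1)) * state(p2, q2), x)
    ana = coherent_overlap([p1], [q1], [p2], [q2], g)
    assert abs(num - ana) < 1e-8


# --------------------------------------------------------------------------
# switching dynamics

def test_switching_between_identical_hamiltonians_is_exact(harmonic_500):
    """H_anh = H_harm: the switch changes nothing about the energy."""
    cfg = ASConfig(t_switch=5000.0, t_sc=1000.0, n_traj=6, seed=3)
    s = ASSCIVRSampler(harmonic_500, cfg)
    P, Q = s.switch()
    w = s.omegas
    e = 0.5 * (P**2).sum(1) + 0.5 * (w**2 * Q**2).sum(1)
    assert np.allclose(e, 0.5 * w.sum(), rtol=1e-10)


def test_switch_transfers_ensemble_toward_morse_zpe(morse_500):
    """After switching, the mean trajectory energy is closer to the Morse
    ZPE than to the harmonic w/2 (adiabatic invariance of the action)."""
    cfg = ASConfig(t_switch=25_000.0, t_sc=1000.0, n_traj=48, seed=4)
    s = ASSCIVRSampler(morse_500, cfg, q_eq=np.zeros(1))
    P, Q = s.switch()
    e = (0.5 * (P**2).sum(1) + s.reduced.value(Q)) * HARTREE_TO_CM1
    e0 = morse_500.zpe_cm1()            # 247.5
    assert abs(e.mean() - e0) < abs(e.mean() - 250.0)


def test_reverse_switch_returns_to_harmonic_shell(morse_500):
    cfg = ASConfig(t_switch=25_000.0, t_sc=1000.0, n_traj=12, seed=5)
    s = ASSCIVRSampler(morse_500, cfg, q_eq=np.zeros(1))
    P, Q = s.switch()
    from nqevib.ascivr import _propagate_switch
    P2, Q2 = _propagate_switch(s.reduced, s.omegas, P, Q,
                               cfg.t_switch, cfg.dt, reverse=True)
    w = s.omegas
    e = (0.5 * (P2**2).sum(1) + 0.5 * (w**2 * Q2**2).sum(1)) * HARTREE_TO_CM1
    assert np.abs(e - 250.0).max() < 5.0


# --------------------------------------------------------------------------
# semiclassical propagation

def test_harmonic_monodromy_and_phase(harmonic_500):
    """Linear dynamics: det M = 1 to 1e-10, no rejections, and the HK phase
    advances as -w t / 2 with continuous branch tracking."""
    cfg = ASConfig(t_switch=1000.0, t_sc=25_000.0, n_traj=4, seed=6)
    s = ASSCIVRSampler(harmonic_500, cfg)
    rng = np.random.default_rng(0)
    P, Q = harmonic_initial_conditions(s.omegas, 4, rng)
    bundle = propagate_semiclassical(s.reduced, s.omegas, P, Q, cfg)
    assert bundle.det_err.max() < 1e-10
    assert bundle.accepted.all()
    w = s.omegas[0]
    expect = -0.5 * w * bundle.times
    assert np.allclose(bundle.hk_phase, expect[None, :], atol=1e-6)


def test_energy_conservation_on_smooth_fixture(morse_500):
    cfg = ASConfig(t_switch=1000.0, t_sc=25_000.0, n_traj=6, seed=7)
    s = ASSCIVRSampler(morse_500, cfg, q_eq=np.zeros(1))
    rng = np.random.default_rng(1)
    P, Q = harmonic_initial_conditions(s.omegas, 6, rng)
    bundle = propagate_semiclassical(s.reduced, s.omegas, P, Q, cfg)
    e = bundle.energy
    drift = np.abs(e - e[:, :1]).max() / e[:, 0].min()
    assert drift < 1e-6


def test_chaotic_fixture_reports_rejections(chaotic_pes):
    """Strong nonlinear coupling at high energy amplifies roundoff in the
    monodromy matrix; some trajectories must fail the 1% determinant test."""
    cfg = ASConfig(t_switch=1000.0, t_sc=25_000.0, n_traj=12, seed=8)
    s = ASSCIVRSampler(chaotic_pes, cfg)
    rng = np.random.default_rng(2)
    # start well above the ZPE shell to reach the chaotic regime
    P, Q = harmonic_initial_conditions(s.omegas, 12, rng)
    bundle = propagate_semiclassical(s.reduced, s.omegas, 3.0 * P, 3.0 * Q,
                                     cfg)
    rate = 1.0 - bundle.accepted.mean()
    assert 0.0 < rate < 1.0


# --------------------------------------------------------------------------
# spectral densities

def test_harmonic_lowest_peak_exact(harmonic_500):
    cfg = ASConfig(t_switch=2000.0, t_sc=25_000.0, n_traj=8, seed=9)
    res = ASSCIVRSampler(harmonic_500, cfg).run()
    assert res.rejection_rate == 0.0
    assert res.zpe_cm1 == pytest.approx(250.0, abs=1.0)


def test_morse_zpe_within_5_wavenumbers(morse_500):
    cfg = ASConfig(t_switch=25_000.0, t_sc=25_000.0, n_traj=24, seed=10)
    res = ASSCIVRSampler(morse_500, cfg, q_eq=np.zeros(1)).run()
    assert abs(res.zpe_cm1 - morse_500.zpe_cm1()) < 5.0


def test_morse_first_excited_peak(morse_500):
    """A weak peak near E1 survives above the window-artifact floor."""
    from nqevib.ascivr import _find_peaks
    cfg = ASConfig(t_switch=25_000.0, t_sc=25_000.0, n_traj=24, seed=10,
                   emax_cm1=1000.0)
    res = ASSCIVRSampler(morse_500, cfg, q_eq=np.zeros(1)).run()
    e1 = morse_500.levels_cm1()[1]      # 727.5
    window = (res.energies_cm1 > 650) & (res.energies_cm1 < 810)
    peaks = _find_peaks(res.energies_cm1[window], res.intensity[window],
                        rel_height=0.2)
    # strongest local maximum in the window sits at the first excited level
    heights = [res.intensity[np.abs(res.energies_cm1 - p).argmin()]
               for p in peaks]
    best = peaks[int(np.argmax(heights))]
    assert best == pytest.approx(e1, abs=10.0)


def test_two_mode_separable_spectrum():
    """ZPE at (w1 + w2)/2; a displaced reference lights up the fundamentals
    at ZPE + w_i (the equilibrium reference is the exact harmonic ground
    state and carries weight on the lowest level only)."""
    pes = HarmonicND([500.0, 730.0], [AMU_TO_ME, AMU_TO_ME])
    cfg = ASConfig(t_switch=2000.0, t_sc=25_000.0, n_traj=24, seed=11,
                   emax_cm1=1600.0)
    sampler = ASSCIVRSampler(pes, cfg)
    res = sampler.run()
    assert res.zpe_cm1 == pytest.approx(615.0, abs=1.0)
    # ground-state reference: one and only one significant peak
    assert res.peaks_cm1.size == 1
    disp = sampler.run(ref_q=0.9 / np.sqrt(sampler.omegas))
    assert disp.zpe_cm1 == pytest.approx(615.0, abs=1.0)
    for target in (615.0, 1115.0, 1345.0):
        assert np.min(np.abs(disp.peaks_cm1 - target)) < 2.0


def test_all_rejected_raises():
    bundle_times = np.arange(3) * 10.0
    from nqevib.ascivr import TrajectoryBundle
    b = TrajectoryBundle(
        times=bundle_times,
        action=np.zeros((2, 3)), hk_phase=np.zeros((2, 3)),
        overlap=np.ones((2, 3), complex), energy=np.zeros((2, 3)),
        det_err=np.array([0.5, 0.9]), accepted=np.array([False, False]))
    with pytest.raises(RuntimeError, match="rejected"):
        spectral_density(b, ASConfig(), emax_cm1=100.0)


def test_torsional_fixture_agrees_with_dvr(torsion_model):
    """Hindered-rotor ZPE from the semiclassical spectrum vs the DVR oracle
    (method uncertainty 20-30 cm^-1)."""
    from nqevib.dvr import RotorSpec, periodic_dvr_1d
    from nqevib.datasets import ETHANOL_I_CH3
    from nqevib.pes import PotentialEvaluator

    cut = torsion_model.cut_methyl(0.0)

    class MethylRotor(PotentialEvaluator):
        # angle coordinate; the inertia plays the role of the mass
        def __init__(self, inertia):
            self.ndim = 1
            self.masses = np.array([inertia])

        def value(self, x):
            return cut(np.asarray(x, float)[..., 0]) / HARTREE_TO_CM1

        def gradient(self, x, step=None):
            a = np.asarray(x, float)[..., 0]
            eps = 1e-6
            d = (cut(a + eps) - cut(a - eps)) / (2 * eps) / HARTREE_TO_CM1
            return d[..., None]

    pes = MethylRotor(ETHANOL_I_CH3)
    dvr = periodic_dvr_1d(cut, ETHANOL_I_CH3, n=161)
    zpe_dvr = dvr.ground_energy - cut.grid_minimum()
    cfg = ASConfig(t_switch=25_000.0, t_sc=25_000.0, n_traj=24, seed=12,
                   emax_cm1=600.0)
    res = ASSCIVRSampler(pes, cfg, q_eq=np.zeros(1)).run()
    assert abs(res.zpe_cm1 - zpe_dvr) < 30.0
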