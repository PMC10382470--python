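"""Delayed characteristic roots, marginal frequencies and wave branches."""

import math

import numpy as np
import pytest

from pcwave.dispersion import (DelayCharacteristic, characteristic_roots,
                               delayed_speeds, dispersion_residual,
                               emergence_threshold, homogeneous_oscillation,
                               homogeneous_residual, marginal_frequencies,
                               max_modulus_map, solve_traveling_waves,
                               trace_branches)
from pcwave.params import Hyperparams

P433 = Hyperparams(0.4, 0.3, 0.3)


# ---------------------------------------------------------------------------
# discrete characteristic equation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("params,k", [
    (P433, 1), (Hyperparams(0.3, 0.1, 0.3), 2), (Hyperparams(0.2, 0.0, 0.5), 3),
])
def test_unit_root_at_theta_zero(params, k):
    roots = characteristic_roots(DelayCharacteristic(params, k), 0.0)
    assert roots.shape == (2 * k + 1,)
    assert np.min(np.abs(roots - 1.0)) < 1e-10


def test_k1_closed_form_roots():
    """k = 1, theta = 0: the non-unit roots are
    -lam/(2(1-beta)) +/- sqrt(lam^2 + 4 alpha (1-beta))/(2(1-beta));
    at alpha + beta + lam = 1 the negative one is exactly -1."""
    roots = np.sort_complex(characteristic_roots(DelayCharacteristic(P433, 1), 0.0))
    a, b, l = P433.as_tuple()
    r_minus = -l / (2 * (1 - b)) - math.sqrt(l ** 2 + 4 * a * (1 - b)) / (2 * (1 - b))
    r_plus = -l / (2 * (1 - b)) + math.sqrt(l ** 2 + 4 * a * (1 - b)) / (2 * (1 - b))
    assert roots[0] == pytest.approx(-1.0, abs=1e-12)
    assert r_minus == pytest.approx(-1.0)
    assert roots[1] == pytest.approx(r_plus, abs=1e-12)
    assert roots[2] == pytest.approx(1.0, abs=1e-12)


def test_roots_sorted_by_modulus():
    roots = characteristic_roots(DelayCharacteristic(P433, 2), 0.7)
    mods = np.abs(roots)
    assert np.all(np.diff(mods) <= 1e-12)


def test_increasing_delay_destabilizes():
    """Raising the delay pushes the spectrum out of the unit disk: at
    (0.3, 0.1, 0.3) the radius is 1 (marginal) for k = 1 and grows beyond 1
    for larger delays."""
    p = Hyperparams(0.3, 0.1, 0.3)
    r1, r5, r8 = (max_modulus_map(DelayCharacteristic(p, k), n_theta=241)
                  for k in (1, 5, 8))
    assert r1 == pytest.approx(1.0, abs=1e-9)
    assert 1.0 + 1e-6 < r5 < r8


# ---------------------------------------------------------------------------
# delayed wave speeds
# ---------------------------------------------------------------------------

def test_delayed_speed_values():
    sp = delayed_speeds(P433, 1)
    assert sp.c0_k == pytest.approx(0.4 / 0.6)
    assert sp.c_tilde0 == pytest.approx(0.4 / 2.2)
    # the secondary speed only exists at k = 1 with alpha+beta+lam = 1
    assert delayed_speeds(Hyperparams(0.3, 0.1, 0.3), 1).c_tilde0 is None
    assert delayed_speeds(P433, 2).c_tilde0 is None


def test_speed_independent_of_delay_when_balanced():
    """alpha = lam: c_0^k = beta/(1-beta) for every k."""
    p = Hyperparams(0.3, 0.4, 0.3)
    for k in (1, 2, 5):
        assert delayed_speeds(p, k).c0_k == pytest.approx(0.4 / 0.6)


def test_speed_pole_guard():
    p = Hyperparams(0.5, 0.2, 0.3)       # pole at k = (1-beta)/(alpha-lam) = 4
    with pytest.raises(ValueError, match="speed undefined"):
        delayed_speeds(p, 4)


# ---------------------------------------------------------------------------
# marginal frequencies
# ---------------------------------------------------------------------------

def test_marginal_frequencies_k1():
    mf = marginal_frequencies(P433, 1)
    assert mf == pytest.approx([0.0, math.pi], abs=1e-9)


def test_marginal_frequencies_k2_tuned_point():
    mf = marginal_frequencies(Hyperparams(0.3, 0.3292, 0.3), 2)
    assert len(mf) == 3
    assert mf[1] == pytest.approx(1.885, abs=2e-3)
    assert mf[2] == pytest.approx(2 * math.pi - mf[1], abs=1e-6)


def test_marginal_frequencies_lie_on_unit_circle_of_roots():
    """Cross-module consistency: each omega corresponds to a characteristic
    root of modulus one at theta = 0."""
    for params, k in [(P433, 1), (Hyperparams(0.3, 0.3292, 0.3), 2)]:
        roots = characteristic_roots(DelayCharacteristic(params, k), 0.0)
        for w in marginal_frequencies(params, k):
            dist = np.min(np.abs(roots - np.exp(1j * w)))
            assert dist < 1e-4


# ---------------------------------------------------------------------------
# homogeneous oscillations
# ---------------------------------------------------------------------------

def test_homogeneous_closed_form_pair():
    tau, omega = homogeneous_oscillation(1.0, 0.2)
    assert tau == pytest.approx(3 * math.pi * 5 / 4)
    assert omega == pytest.approx(0.4)
    assert 1000 * omega / (2 * math.pi) == pytest.approx(63.66, abs=0.01)
    assert homogeneous_residual(1.0, 0.2, tau, omega) < 1e-12


def test_homogeneous_absent_beyond_three():
    assert homogeneous_oscillation(3.5, 0.2) is None
    assert homogeneous_oscillation(3.0, 0.2) is None


def test_homogeneous_smallest_tau_at_first_branch():
    t1, _ = homogeneous_oscillation(0.7, 0.2, branch_k=1)
    t2, _ = homogeneous_oscillation(0.7, 0.2, branch_k=2)
    assert 0 < t1 < t2


# ---------------------------------------------------------------------------
# traveling waves
# ---------------------------------------------------------------------------

def test_rho0_no_solution_below_threshold():
    assert solve_traveling_waves(0.0, 1.0 / 50.0, 10.0) == []


def test_rho0_solution_and_theta_formula():
    sols = solve_traveling_waves(0.0, 1.0 / 15.0, 12.0)
    assert len(sols) == 1
    s = sols[0]
    assert s.omega == pytest.approx(2 * (1 / 15) * math.sin(2 * s.omega * 12.0),
                                    abs=1e-10)
    assert s.theta == pytest.approx((-3 * s.omega * 12.0) % (2 * math.pi))


def test_rho1_closed_form_pair():
    sols = solve_traveling_waves(1.0, 1.0 / 20.0, 20.0)
    assert len(sols) == 2
    th = math.acos(-math.pi / 4)
    for s in sols:
        assert s.omega == pytest.approx(math.pi / 40)
        assert s.freq_hz == pytest.approx(12.5)
    assert sols[0].theta == pytest.approx(th)
    assert sols[1].theta == pytest.approx(2 * math.pi - th)
    assert sols[0].direction == "backward"
    assert sols[1].direction == "forward"
    # theta values are symmetric about pi
    assert sols[0].theta + sols[1].theta == pytest.approx(2 * math.pi)


def test_rho1_absent_below_pi_threshold():
    assert solve_traveling_waves(1.0, 1.0 / 30.0, 20.0) == []


def test_example_pair_at_rho_0633():
    """The printed example: (omega, theta) ~ (0.12, 2.82) backward and
    (0.08, 4.60) forward at rho = 0.633, tau = 12 ms, 1/alpha_t = 15 ms."""
    sols = solve_traveling_waves(0.633, 1.0 / 15.0, 12.0)
    assert len(sols) == 2
    prim = next(s for s in sols if s.branch == "primary")
    sec = next(s for s in sols if s.branch == "secondary")
    assert prim.omega == pytest.approx(0.12, abs=0.005)
    assert prim.theta == pytest.approx(2.82, abs=0.01)
    assert prim.direction == "backward"
    assert sec.omega == pytest.approx(0.08, abs=0.005)
    assert sec.theta == pytest.approx(4.60, abs=0.01)
    assert sec.direction == "forward"


def test_every_solution_zeroes_full_system():
    for rho in (0.0, 0.3, 0.633, 1.0, 1.02):
        for s in solve_traveling_waves(rho, 1.0 / 15.0, 12.0):
            assert dispersion_residual(rho, 1.0 / 15.0, 12.0,
                                       s.omega, s.theta) < 1e-10


@pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
def test_existence_threshold_below_one(rho):
    """rho < 1: nontrivial solutions appear through either mechanism --
    the slope condition 4 a t > (1+rho)/(1-rho) (root peeling off omega = 0)
    or the tangency condition 4 a t >= pi - arccos(2 rho/(1+rho^2)).  Below
    both bounds no solution exists; above either bound one does."""
    tangency = math.pi - math.acos(2 * rho / (1 + rho ** 2))
    slope = (1 + rho) / (1 - rho)
    tau = 10.0
    at_low = (min(tangency, slope) * 0.95) / (4 * tau)
    assert solve_traveling_waves(rho, at_low, tau) == []
    at_high = (min(tangency, slope) * 1.1) / (4 * tau)
    assert len(solve_traveling_waves(rho, at_high, tau)) >= 1


@pytest.mark.parametrize("rho", [1.3, 2.0])
def test_existence_threshold_above_one(rho):
    """No nontrivial solution when 4 a t < pi + arccos(2 rho/(1+rho^2))."""
    bound = math.pi + math.acos(2 * rho / (1 + rho ** 2))
    tau = 10.0
    at_low = (bound * 0.95) / (4 * tau)
    assert solve_traveling_waves(rho, at_low, tau) == []
    at_high = (bound * 1.2) / (4 * tau)
    assert len(solve_traveling_waves(rho, at_high, tau)) >= 1


# ---------------------------------------------------------------------------
# branch continuation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trace_15():
    grid = np.round(np.arange(0.0, 1.2001, 0.01), 10)
    return trace_branches(1.0 / 15.0, 12.0, grid)


def test_emergence_threshold_formula(trace_15):
    assert trace_15.rho_c == pytest.approx((3.2 - 1) / (3.2 + 1))
    assert emergence_threshold(1.0 / 15.0, 12.0) == pytest.approx(0.5238, abs=1e-4)
    # detected emergence agrees with the analytic threshold to the grid step
    assert abs(trace_15.rho_c_detected - trace_15.rho_c) <= 0.011


def test_fold_location(trace_15):
    assert trace_15.rho_0 == pytest.approx(1.06, abs=0.01)


def test_primary_branch_theta_nearly_constant(trace_15):
    """The primary branch keeps theta in (0, pi), close to 2.82."""
    thetas = [s.theta for s in trace_15.primary]
    assert all(0 < t < math.pi for t in thetas)
    early = [s.theta for s in trace_15.primary if s.rho_ratio < 0.9]
    assert max(abs(t - 2.82) for t in early) < 0.1


def test_branches_cross_at_rho_one(trace_15):
    at_one = [s for s in trace_15.samples if abs(s.rho_ratio - 1.0) < 1e-9]
    assert len(at_one) == 2
    for s in at_one:
        assert s.omega == pytest.approx(math.pi / (2 * 12.0))
    assert at_one[0].theta + at_one[1].theta == pytest.approx(2 * math.pi)


def test_second_example_fold_and_direction_flip():
    grid = np.round(np.arange(0.0, 3.5001, 0.02), 10)
    tr = trace_branches(1.0 / 12.0, 12.0, grid)
    assert tr.rho_0 == pytest.approx(3.03, abs=0.06)
    assert tr.flip_rho == pytest.approx(1.65, abs=0.04)
    # beyond the flip the secondary branch propagates backward at a higher
    # temporal frequency than the primary
    late_sec = [s for s in tr.secondary if 2.0 < s.rho_ratio < 2.5]
    late_prim = [s for s in tr.primary if 2.0 < s.rho_ratio < 2.5]
    assert all(s.direction == "backward" for s in late_sec)
    assert np.mean([s.omega for s in late_sec]) > np.mean(
        [s.omega for s in late_prim])


def test_coarse_grid_refused():
    with pytest.raises(ValueError, match="too coarse"):
        trace_branches(1.0 / 15.0, 12.0, np.array([0.0, 0.2, 0.4]))
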