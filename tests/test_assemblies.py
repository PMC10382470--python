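"""Assembly decomposition, residual Laplacians and the orientation ring."""

import math

import numpy as np
import pytest

from pcwave.assemblies import (DecompositionError, build_conv_residual,
                               build_ring_model, decompose_pair,
                               periodic_laplacian_spectrum, ring_eigenvectors,
                               ring_mode_summary, ring_sigma0, transform)
from pcwave.fields import SpaceTimeField
from pcwave.fixtures import make_fixture
from pcwave.lattice import simulate_lattice, simulate_matrix
from pcwave.params import GainPair, Hyperparams

RING_PARAMS = Hyperparams(0.1, 0.1, 0.5)


# ---------------------------------------------------------------------------
# joint diagonalization
# ---------------------------------------------------------------------------

def test_identity_pair_decomposition():
    basis = decompose_pair(np.eye(4), np.eye(4))
    assert np.allclose(basis.gains_f, 1.0)
    assert np.allclose(basis.gains_b, 1.0)
    assert np.allclose(basis.P.T @ basis.P, np.eye(4), atol=1e-12)


def test_seeded_pair_recovers_gains():
    fix = make_fixture("random_symmetric_pair", 8, seed=5)
    Wf, Wb = fix.payload["Wf"], fix.payload["Wb"]
    basis = decompose_pair(Wf, Wb)
    assert np.allclose(np.sort(basis.gains_f), np.sort(fix.payload["gains_f"]),
                       atol=1e-10)
    assert np.allclose(np.sort(basis.gains_b), np.sort(fix.payload["gains_b"]),
                       atol=1e-10)
    # reconstruction and orthogonality
    assert np.abs(basis.P @ np.diag(basis.gains_f) @ basis.P.T - Wf).max() < 1e-10
    assert np.abs(basis.P @ np.diag(basis.gains_b) @ basis.P.T - Wb).max() < 1e-10
    assert np.abs(basis.P.T @ basis.P - np.eye(8)).max() < 1e-10
    # ordering and sign conventions are deterministic
    assert np.all(np.diff(basis.gains_b) >= -1e-12)


def test_noncommuting_pair_rejected():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(4, 4)); A = A + A.T
    B = rng.normal(size=(4, 4)); B = B + B.T
    with pytest.raises(DecompositionError, match="commute"):
        decompose_pair(A, B)


def test_asymmetric_matrix_rejected():
    with pytest.raises(DecompositionError, match="asymmetric"):
        decompose_pair(np.array([[0.0, 1.0], [0.0, 0.0]]), np.eye(2))


def test_transform_roundtrip_and_energy():
    fix = make_fixture("random_symmetric_pair", 5, seed=1)
    basis = decompose_pair(fix.payload["Wf"], fix.payload["Wb"])
    rng = np.random.default_rng(2)
    field = SpaceTimeField(rng.normal(size=(7, 9, 5)))
    u = transform(field, basis, "to_assemblies")
    back = transform(u, basis, "from_assemblies")
    assert np.max(np.abs(back.values - field.values)) < 1e-12
    energy_e = (field.values ** 2).sum(axis=2)
    energy_u = (u.values ** 2).sum(axis=2)
    assert np.max(np.abs(energy_e - energy_u)) < 1e-12


def test_matrix_simulation_decouples_into_scalar_assembly_runs():
    """The oracle check: a full-matrix run transformed to the assembly basis
    equals stacked scalar lattice runs with gains (gamma_p^f, gamma_p^b)."""
    fix = make_fixture("random_symmetric_pair", 4, seed=9)
    Wf, Wb = 0.5 * fix.payload["Wf"], 0.5 * fix.payload["Wb"]
    p = Hyperparams(0.3, 0.2, 0.3)
    basis = decompose_pair(Wf, Wb)
    J, n = 60, 30
    rng = np.random.default_rng(4)
    source = rng.normal(size=4)
    init = np.zeros((J + 1, 4))
    init[0] = source
    fm = simulate_matrix(init, Wf, Wb, p, source, n)
    u = transform(fm, basis, "to_assemblies")
    src_u = basis.P.T @ source
    for q in range(4):
        init_q = np.zeros(J + 1)
        init_q[0] = src_u[q]
        fs = simulate_lattice(init_q, p, basis.gain_pair(q), n,
                              domain="semi_infinite", source=src_u[q],
                              certify=False)
        JJ = 25    # J - JJ > n: neither top boundary is causally visible
        assert np.max(np.abs(u.values[:, :JJ, q] - fs.values[:, :JJ, 0])) < 1e-10


# ---------------------------------------------------------------------------
# residual Laplacian matrices
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("d", [3, 5, 8, 16, 33, 64])
def test_dirichlet_spectrum_closed_form(d):
    cr = build_conv_residual(d, 0.3, 0.7, "dirichlet")
    numeric = np.sort(np.linalg.eigvalsh(cr.A))
    assert np.max(np.abs(numeric - np.sort(cr.spectrum_A))) < 1e-10
    assert np.max(np.abs(np.sort(np.linalg.eigvalsh(cr.W))
                         - np.sort(cr.spectrum_W))) < 1e-10


def test_dirichlet_d3_explicit_spectrum():
    cr = build_conv_residual(3, 0.0, 1.0, "dirichlet")
    expect = np.array([-2 - math.sqrt(2), -2.0, -2 + math.sqrt(2)])
    assert np.max(np.abs(np.sort(cr.spectrum_A) - expect)) < 1e-12


def test_dirichlet_normalization_maps_extremes_to_unit():
    for d in (4, 9, 32):
        cr = build_conv_residual(d, 0.0, 1.0, "dirichlet")
        zs, xs = cr.zeta_star, cr.xi_star
        lo = zs - 4 * xs * math.sin(d * math.pi / (2 * (d + 1))) ** 2
        hi = zs - 4 * xs * math.sin(math.pi / (2 * (d + 1))) ** 2
        assert lo == pytest.approx(-1.0, abs=1e-12)
        assert hi == pytest.approx(1.0, abs=1e-12)
        norm = build_conv_residual(d, zs, xs, "dirichlet")
        inner = np.sort(norm.spectrum_W)[1:-1]
        assert np.all((inner > -1) & (inner < 1))


@pytest.mark.parametrize("d", [4, 6, 16, 32])
def test_periodic_spectrum_closed_form(d):
    cr = build_conv_residual(d, 0.0, 1.0, "periodic")
    numeric = np.sort(np.linalg.eigvalsh(cr.A))
    assert np.max(np.abs(numeric - np.sort(cr.spectrum_A))) < 1e-10


def test_periodic_d4_multiplicities():
    spec = sorted(periodic_laplacian_spectrum(4))
    assert spec == pytest.approx([-4.0, -2.0, -2.0, 0.0])


# ---------------------------------------------------------------------------
# ring model
# ---------------------------------------------------------------------------

def test_ring_eigenvectors_diagonalize_wb():
    d = 32
    P = ring_eigenvectors(d)
    assert np.abs(P.T @ P - np.eye(d)).max() < 1e-12
    ring = build_ring_model(d, RING_PARAMS)
    D = P.T @ ring.Wb @ P
    assert np.abs(D - np.diag(np.diag(D))).max() < 1e-12
    assert np.allclose(np.diag(D), ring.gains_b, atol=1e-12)


def test_ring_gain_range():
    ring = build_ring_model(32, RING_PARAMS)
    assert ring.gains_b[0] == pytest.approx(0.5)
    assert ring.gains_b[-1] == pytest.approx(1.5)
    # gains are 1/2 + sin^2(p pi / d) pairwise
    assert ring.gains_b[1] == pytest.approx(0.5 + math.sin(math.pi / 32) ** 2)


def test_ring_speed_ordering_and_sign_pattern():
    """Exactly 7 positive modes at d=32, (0.1, 0.1, 0.5), with paired speeds
    and monotone decrease in p."""
    ring = build_ring_model(32, RING_PARAMS)
    sp = ring.speeds
    assert np.all(np.diff(sp) <= 1e-12)
    assert int(np.sum(sp > 0)) == 7
    assert sp[7] < 0 < sp[6]
    assert sp[7] == pytest.approx(sp[8])
    assert sp[5] == pytest.approx(sp[6])
    assert sp[1] == pytest.approx(sp[2])
    assert sp[2] < sp[0]


def test_ring_wf_symmetric_and_excitatory_at_reference_point():
    ring = build_ring_model(32, RING_PARAMS)
    assert np.abs(ring.Wf - ring.Wf.T).max() < 1e-12
    assert ring.Wf.min() > -1e-12      # purely excitatory at this point only


def test_ring_sigma_matches_identity_at_unit_gain():
    s = ring_sigma0(RING_PARAMS, 1.0)
    assert s == pytest.approx(0.48 / (2 * 0.81))


def test_ring_requires_beta_positive_and_even_d():
    with pytest.raises(ValueError):
        build_ring_model(32, Hyperparams(0.1, 0.0, 0.5))
    with pytest.raises(ValueError):
        build_ring_model(31, RING_PARAMS)


def test_cosine_plane_combination():
    """a U_{2p} + b U_{2p+1} is a translated cosine profile of amplitude
    sqrt(a^2 + b^2) (on the normalized columns, checked componentwise)."""
    d = 32
    P = ring_eigenvectors(d)
    p = 2
    a_coef, b_coef = 0.8, -1.3
    combo = a_coef * P[:, 2 * p - 1] + b_coef * P[:, 2 * p]
    norm = math.sqrt(2.0 / d)          # column normalization of cos/sin
    A = math.sqrt(a_coef ** 2 + b_coef ** 2)
    phi = -math.atan2(b_coef, a_coef)   # phi = -arctan(b/a)
    k = np.arange(1, d + 1)
    expect = A * norm * np.cos(2 * k * p * math.pi / d + phi)
    assert np.max(np.abs(combo - expect)) < 1e-12


def test_ring_stationary_profile_has_zero_residual():
    """The geometric sequence a_p ((alpha g + beta chi(g))/(lam g))^j is a
    stationary solution of the per-assembly recurrence."""
    ring = build_ring_model(32, RING_PARAMS)
    a, b, l = RING_PARAMS.as_tuple()
    p = 10                              # a blocked mode, c_0^p < 0
    assert ring.speeds[p] < 0
    g, cg = ring.gains_b[p], ring.gains_f[p]
    ratio = (a * g + b * cg) / (l * g)
    prof = ratio ** np.arange(40)
    stepped = simulate_lattice(prof, RING_PARAMS, GainPair(cg, g), 1,
                               domain="semi_infinite", source=1.0,
                               certify=False)
    J = min(40, stepped.n_layers) - 2
    resid = stepped.values[1, :J, 0] - ratio ** np.arange(J)
    assert np.max(np.abs(resid)) < 1e-12


def test_ring_acts_as_mode_filter():
    """Non-propagating assemblies (p >= 8) are suppressed deep in the
    network below their input projection scaled by the stationary ratio."""
    ring = build_ring_model(32, RING_PARAMS)
    fix = make_fixture("tuned_plus_noise", 32, seed=7)
    coeffs = fix.payload["coeffs"]
    summary = ring_mode_summary(ring, coeffs, n=200, J=8)
    j_probe = 5
    prof = summary.reconstruction.values[200, j_probe, :]
    proj = ring.P.T @ prof
    a, b, l = RING_PARAMS.as_tuple()
    for p in range(7, 32):
        if coeffs[p] == 0.0 or ring.speeds[p] >= 0:
            continue
        g, cg = ring.gains_b[p], ring.gains_f[p]
        ratio = (a * g + b * cg) / (l * g)
        bound = abs(coeffs[p]) * ratio ** j_probe
        assert abs(proj[p]) <= bound * (1 + 1e-6)
    # and the propagating tuned mode survives at full strength
    assert proj[1] > 0.9 * coeffs[1]


def test_ring_coarse_to_fine_arrival():
    """The constant mode's front reaches a deep layer before a slower
    mid-frequency mode, matching the ordering of the closed-form speeds."""
    ring = build_ring_model(32, RING_PARAMS)
    coeffs = np.zeros(32)
    coeffs[0] = 1.0
    coeffs[8] = 1.0                    # p index 8: slower mode (c ~ small)
    n = 150
    summary = ring_mode_summary(ring, coeffs, n=n, J=12)
    j_probe = 10

    def arrival(run):
        tl = run.field.scalar[:, j_probe]
        above = np.nonzero(tl > run.coeff / 4)[0]
        return above[0] if above.size else np.inf

    t_fast = arrival(summary.modes[0])
    t_slow = arrival(summary.modes[8])
    assert t_fast < t_slow
    # predicted arrival ordering from the closed-form speeds
    assert ring.speeds[0] > ring.speeds[8]


def test_full_matrix_ring_equals_assembly_runs():
    """Full d-channel ring simulation agrees with the per-assembly scalar
    runs through the P transform."""
    d = 8
    params = Hyperparams(0.1, 0.1, 0.5)
    ring = build_ring_model(d, params)
    rng = np.random.default_rng(12)
    e0 = rng.normal(size=d)
    J, n = 45, 25
    # keep the matrix run's top boundary causally invisible from the probed
    # layers: feedback travels one layer per step, J - probe > n
    init = np.zeros((J + 1, d))
    init[0] = e0
    fm = simulate_matrix(init, ring.Wf, ring.Wb, params, e0, n)
    u = transform(fm, ring.basis(), "to_assemblies")
    a_p = ring.P.T @ e0
    for q in range(d):
        init_q = np.zeros(J + 1)
        init_q[0] = a_p[q]
        fs = simulate_lattice(init_q, params, ring.gain_pair(q), n,
                              domain="semi_infinite", source=a_p[q],
                              certify=False)
        JJ = 15
        assert np.max(np.abs(u.values[:, :JJ, q] - fs.values[:, :JJ, 0])) < 1e-10
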