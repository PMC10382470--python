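"""Continuous-time and fully continuous limits of the lattice model.

Rescaling the discrete gains by the time step (alpha_t = alpha/dt, ...) and
letting dt -> 0 turns the recurrence into a linear lattice ODE whose
fundamental solution is a drifting Gaussian with speed
c~0 = beta_t + alpha_t - lambda_t and spread (beta_t+alpha_t+lambda_t)/2.
Making depth continuous as well yields a transport equation (advection
nu*c0), or -- exactly at the balance beta + alpha = lam -- a heat equation
whose diffusivity is delta*sigma0.  With transmission delays the lattice ODE
becomes a delay differential equation integrated here by the method of
steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad, solve_ivp

from .amplification import identity_speeds
from .fields import SpaceTimeField
from .lattice import TruncationError
from .params import GainPair, Hyperparams, ScaledParams

_EDGE_TOL = 1e-10


def _ode_coefficients(scaled: ScaledParams, gains: GainPair):
    """(sub, diag, sup) coefficients of the lattice ODE d/dt u_j."""
    at, bt, lt = scaled.alpha_t, scaled.beta_t, scaled.lambda_t
    g1, g2 = gains.gamma_f, gains.gamma_b
    return (bt * g1 + at * g2,
            -(bt + lt + at * g2 ** 2),
            lt * g2)


def integrate_lattice_ode(initial: np.ndarray,
                          scaled: ScaledParams,
                          gains: GainPair = GainPair.identity(),
                          t_end: float = 1.0,
                          dt_out: float = 1.0,
                          j_initial: int = 0,
                          rtol: float = 1e-10,
                          atol: float = 1e-12) -> SpaceTimeField:
    """Integrate the linear lattice ODE on a certified truncated window."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    initial = np.asarray(initial, dtype=float)
    sub, diag, sup = _ode_coefficients(scaled, gains)
    drift = sub - sup
    spread = 0.5 * (abs(sub) + abs(sup))
    margin_r = int(math.ceil(max(1.0, drift + 6 * spread + 1.0) * t_end)) + 8
    margin_l = int(math.ceil(max(1.0, -drift + 6 * spread + 1.0) * t_end)) + 8
    nz = np.nonzero(initial)[0]
    lo = int(nz[0]) if nz.size else 0
    hi = int(nz[-1]) if nz.size else 0
    jlo = j_initial + lo - margin_l
    jhi = j_initial + hi + margin_r
    J = jhi - jlo + 1
    u0 = np.zeros(J)
    u0[j_initial + lo - jlo:j_initial + hi - jlo + 1] = initial[lo:hi + 1]

    def rhs(_t, u):
        du = diag * u
        du[1:] += sub * u[:-1]
        du[:-1] += sup * u[1:]
        return du

    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(rhs, (0.0, t_end), u0, method="DOP853",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"lattice ODE integration failed: {sol.message}")
    field = SpaceTimeField(sol.y.T, j_offset=jlo, domain="infinite_truncated",
                           times=sol.t)
    if field.edge_magnitude() > _EDGE_TOL:
        raise TruncationError("domain too small for the lattice ODE run")
    return field


# ---------------------------------------------------------------------------
# closed-form PDE solutions
# ---------------------------------------------------------------------------

@dataclass
class PdeSpec:
    """Continuum limit on the half line x > 0.

    ``transport``: advection at nu*c0 with source trace entering from x = 0
    when c0 > 0.  ``heat``: the balanced case beta + alpha = lam, diffusivity
    ``diffusion`` = delta*sigma0, solved with the image (odd-reflection)
    kernel.  ``boundary`` is the constant source value s0; ``initial`` an
    optional profile h(x).
    """

    kind: str                               # transport | heat
    advection: float = 0.0                  # nu * c0
    diffusion: float = 0.0                  # delta * sigma0
    boundary: float = 0.0                   # constant source s0
    initial: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("transport", "heat"):
            raise ValueError(f"unknown PDE kind {self.kind!r}")
        if self.kind == "heat" and self.diffusion <= 0:
            raise ValueError("unstable continuum limit: diffusion must be > 0")


def _heat_kernel(t: float, x: float, y, D: float):
    y = np.asarray(y, dtype=float)
    z = 4.0 * D * t
    return (np.exp(-(x - y) ** 2 / z) - np.exp(-(x + y) ** 2 / z)) / math.sqrt(math.pi * z)


def closed_form_pde(spec: PdeSpec, t: float, x: float) -> float:
    """Evaluate the closed-form continuum solution at (t, x).

    Transport: characteristics (the c0 < 0 branch ignores the source -- the
    boundary trace is set by the initial data alone).  Heat: constant-source
    erf profile plus the image-kernel integral of the initial profile,
    evaluated by adaptive quadrature truncated at eight standard deviations.
    """
    if t <= 0 or x < 0:
        raise ValueError("require t > 0 and x >= 0")
    h = spec.initial or (lambda _x: 0.0)
    if spec.kind == "transport":
        c = spec.advection
        if c < 0:
            return float(h(x - c * t))
        if c == 0:
            return float(h(x))
        if x <= c * t:
            return float(spec.boundary)      # constant source s0(t - x/c) = s0
        return float(h(x - c * t))
    D = spec.diffusion
    out = spec.boundary * (1.0 - math.erf(x / math.sqrt(4.0 * D * t)))
    if spec.initial is not None:
        width = 8.0 * math.sqrt(2.0 * D * t)
        lo, hi = max(0.0, x - width), x + width
        val, _err = quad(lambda y: _heat_kernel(t, x, y, D) * h(y), lo, hi,
                         epsabs=1e-10, limit=200)
        out += val
    return float(out)


def heat_spec_from_params(params: Hyperparams, delta: float,
                          s0: float = 1.0,
                          initial: Optional[Callable] = None) -> PdeSpec:
    """Heat-equation spec for the balanced case beta + alpha = lam."""
    if abs(params.beta + params.alpha - params.lam) > 1e-12:
        raise ValueError("heat limit requires beta + alpha = lam")
    sigma0 = identity_speeds(params)["sigma0"]
    return PdeSpec(kind="heat", diffusion=delta * sigma0, boundary=s0,
                   initial=initial)


@dataclass(frozen=True)
class WidthDiffusion:
    coefficient: float
    stable: bool


def width_diffusion_coefficient(params: Hyperparams, xi_f: float, xi_b: float,
                                kappa: float = 1.0) -> WidthDiffusion:
    """Diffusivity along layer width for residual-Laplacian connectivity.

    For Wf = I + xi_f A, Wb = I + xi_b A the fully continuous limit diffuses
    along the width coordinate with coefficient
    kappa * (beta*xi_f + (lam - alpha)*xi_b) / (1 - beta); the limit is well
    posed only when the coefficient is nonnegative (for xi_f = xi_b = xi
    this is the sign condition xi * (beta + lam - alpha) >= 0).
    """
    a, b, l = params.alpha, params.beta, params.lam
    coeff = kappa * (b * xi_f + (l - a) * xi_b) / (1.0 - b)
    return WidthDiffusion(coefficient=coeff, stable=coeff >= 0.0)


# ---------------------------------------------------------------------------
# delayed lattice ODE (method of steps)
# ---------------------------------------------------------------------------

def integrate_delayed_lattice_ode(history: Callable[[float], np.ndarray],
                                  scaled: ScaledParams,
                                  tau: float,
                                  t_end: float,
                                  homogeneous: bool = False,
                                  n_layers: int = 1,
                                  periodic: bool = False,
                                  dt_out: Optional[float] = None,
                                  rtol: float = 1e-10,
                                  atol: float = 1e-12) -> SpaceTimeField:
    """Integrate the delayed lattice ODE by the method of steps.

    The delayed model is

        d/dt e_j(t) = beta_t e_{j-1}(t) - (beta_t + lambda_t) e_j(t)
                      + alpha_t e_{j-1}(t - tau) + lambda_t e_{j+1}(t - tau)
                      - alpha_t e_j(t - 2 tau),

    with ``history(t)`` defined on [-2 tau, 0] returning the layer vector
    (or a scalar for ``homogeneous=True``, which integrates the
    layer-independent reduction).  Integration proceeds tau-interval by
    tau-interval with the integrator's dense output serving as the (cubic)
    history interpolant; the step size is capped at tau / 20.

    ``periodic=True`` closes the layers into a ring, the setting used for
    traveling-wave persistence experiments (a modeling choice: the
    infinite-lattice wave ansatz is periodic in j once theta is a rational
    multiple of 2 pi, and a ring avoids boundary reflections).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    at, bt, lt = scaled.alpha_t, scaled.beta_t, scaled.lambda_t
    dim = 1 if homogeneous else n_layers

    h0 = np.atleast_1d(np.asarray(history(-2.0 * tau), dtype=float))
    if h0.shape != (dim,):
        raise ValueError(f"history must return {dim} values, got {h0.shape}")

    segments: list = []            # (t_lo, t_hi, OdeSolution)

    def lookup(t: float) -> np.ndarray:
        if t <= 0.0:
            return np.atleast_1d(np.asarray(history(t), dtype=float))
        for t_lo, t_hi, interp in segments:
            if t_lo - 1e-12 <= t <= t_hi + 1e-12:
                return interp(min(max(t, t_lo), t_hi))
        raise RuntimeError(f"history gap at t = {t}")

    if homogeneous:
        def rhs(t, u):
            return (-lt * u + (at + lt) * lookup(t - tau)
                    - at * lookup(t - 2.0 * tau))
    else:
        def rhs(t, u):
            u1 = lookup(t - tau)
            u2 = lookup(t - 2.0 * tau)
            if periodic:
                um1_now = np.roll(u, 1)
                um1_tau = np.roll(u1, 1)
                up1_tau = np.roll(u1, -1)
            else:
                um1_now = np.concatenate([[0.0], u[:-1]])
                um1_tau = np.concatenate([[0.0], u1[:-1]])
                up1_tau = np.concatenate([u1[1:], [0.0]])
            return (bt * um1_now - (bt + lt) * u
                    + at * um1_tau + lt * up1_tau - at * u2)

    u = np.atleast_1d(np.asarray(history(0.0), dtype=float)).copy()
    t0 = 0.0
    n_seg = int(math.ceil(t_end / tau))
    for _ in range(n_seg):
        t1 = min(t0 + tau, t_end)
        sol = solve_ivp(rhs, (t0, t1), u, method="RK45", dense_output=True,
                        max_step=tau / 20.0, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"delayed ODE integration failed: {sol.message}")
        segments.append((t0, t1, sol.sol))
        u = sol.y[:, -1]
        t0 = t1

    dt_out = dt_out or tau / 20.0
    t_samp = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_samp = np.minimum(t_samp[t_samp <= t_end + 0.5 * dt_out], t_end)
    vals = np.stack([lookup(float(t)) for t in t_samp])
    field = SpaceTimeField(vals[:, :, None] if vals.ndim == 2 else vals,
                           j_offset=0, domain="infinite_truncated",
                           times=t_samp)
    field.meta["tau_ms"] = tau
    field.meta["periodic"] = periodic
    field.meta["homogeneous"] = homogeneous
    return field
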