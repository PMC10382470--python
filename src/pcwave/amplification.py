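"""Amplification-factor (von Neumann) analysis of the lattice recurrence.

For a spatial Fourier mode ``e^{i j theta}`` the one-step temporal gain of
the recurrence is the complex amplification factor

    rho(theta) = [alpha*g2*(e^{-i theta} - g2) + 1 - beta
                  + lam*(g2*e^{i theta} - 1)] / (1 - beta*g1*e^{-i theta}),

with assembly gains ``(g1, g2)``; ``(1, 1)`` is the identity-connectivity
case, ``(g, g)`` the symmetric Rao-Ballard case.  Stability of the infinite
lattice is read from ``max_theta |rho|``: strictly below one means decay,
above one blow-up, and tangency points ``|rho(theta_0)| = 1`` carry traveling
Gaussian wave packets whose drift (wave speed) and diffusive spread are the
first two coefficients of ``log rho`` around ``theta_0``.

This module also provides the closed-form boundary objects of the symmetric
analysis: the quadratic roots ``gamma_pm^0`` where ``rho_gamma(0) = -1``, the
``chi``/``zeta`` curves where ``rho_{g1,g2}(0) = +/-1``, the five-region
partition of the ``(beta, lam)`` quadrant, and the continuous-time
amplification factor ``nu``.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .params import GainPair, Hyperparams, ScaledParams

_MARGIN_TOL = 1e-10


class ModeAbsentError(ValueError):
    """Requested wave mode has no tangency point."""


# ---------------------------------------------------------------------------
# amplification factors
# ---------------------------------------------------------------------------

def rho(theta, params: Hyperparams, gains: GainPair = GainPair.identity()):
    """Evaluate the amplification factor; vectorizes over ``theta``."""
    gains.check_pole(params)
    a, b, l = params.alpha, params.beta, params.lam
    g1, g2 = gains.gamma_f, gains.gamma_b
    th = np.asarray(theta, dtype=float)
    em = np.exp(-1j * th)
    ep = np.exp(1j * th)
    num = a * g2 * (em - g2) + (1.0 - b) + l * (g2 * ep - 1.0)
    den = 1.0 - b * g1 * em
    out = num / den
    if np.ndim(theta) == 0:
        return complex(out)
    return out


def continuous_nu(theta, scaled: ScaledParams,
                  gains: GainPair = GainPair.identity()):
    """Continuous-time amplification factor nu(theta) of the lattice ODE."""
    at, bt, lt = scaled.alpha_t, scaled.beta_t, scaled.lambda_t
    g1, g2 = gains.gamma_f, gains.gamma_b
    th = np.asarray(theta, dtype=float)
    out = ((bt * g1 + at * g2) * np.exp(-1j * th)
           - (bt + lt + at * g2 ** 2)
           + lt * g2 * np.exp(1j * th))
    if np.ndim(theta) == 0:
        return complex(out)
    return out


def continuous_stability(scaled: ScaledParams,
                         gains: GainPair = GainPair.identity(),
                         grid_size: int = 4096) -> dict:
    """Max of Re(nu) over theta with the closed-form marginal boundaries.

    Stability of the lattice ODE requires ``max Re(nu) <= 0``.  For positive
    effective coupling the maximum sits at theta=0, otherwise at theta=pi;
    both closed forms are returned alongside the grid maximum.
    """
    th = np.linspace(-math.pi, math.pi, grid_size)
    re = continuous_nu(th, scaled, gains).real
    at, bt, lt = scaled.alpha_t, scaled.beta_t, scaled.lambda_t
    g1, g2 = gains.gamma_f, gains.gamma_b
    re0 = bt * g1 + (at + lt) * g2 - (bt + lt + at * g2 ** 2)
    repi = -(bt * g1 + (at + lt) * g2) - (bt + lt + at * g2 ** 2)
    closed = max(re0, repi)
    return {
        "max_re": float(max(np.max(re), closed)),
        "re_at_0": float(re0),
        "re_at_pi": float(repi),
        "stable": bool(max(np.max(re), closed) <= _MARGIN_TOL),
    }


# ---------------------------------------------------------------------------
# stability classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityVerdict:
    status: str  # stable | unstable | marginally_stable
    max_modulus: float
    tangency_thetas: tuple[float, ...] = field(default_factory=tuple)


def classify_stability(params: Hyperparams,
                       gains: GainPair = GainPair.identity(),
                       grid_size: int = 4096) -> StabilityVerdict:
    """Classify |rho| on a uniform theta grid over [-pi, pi].

    ``marginally_stable`` means the grid maximum equals one to 1e-10 with the
    tangency points isolated on the grid.  For identity gains the result is
    cross-checked against the closed criterion (max|rho| <= 1 iff
    alpha + lam <= 1, tangency at pi iff alpha + lam = 1).
    """
    if grid_size < 721:
        raise ValueError("grid_size must be at least 721")
    th = np.linspace(-math.pi, math.pi, grid_size)
    mod = np.abs(rho(th, params, gains))
    # exact endpoint checks
    special = np.array([0.0, math.pi, -math.pi])
    mod_special = np.abs(rho(special, params, gains))
    max_mod = float(max(mod.max(), mod_special.max()))

    if max_mod > 1.0 + _MARGIN_TOL:
        status = "unstable"
        tangencies: tuple[float, ...] = ()
    else:
        near = th[mod >= 1.0 - _MARGIN_TOL]
        for t0, m0 in zip(special, mod_special):
            if m0 >= 1.0 - _MARGIN_TOL:
                near = np.append(near, t0)
        if near.size == 0:
            status = "stable"
            tangencies = ()
        else:
            status = "marginally_stable"
            tangencies = _cluster_tangencies(near, spacing=th[1] - th[0])

    if gains.is_identity:
        _cross_check_identity(params, status, tangencies)
    return StabilityVerdict(status, max_mod, tangencies)


def _cluster_tangencies(near: np.ndarray, spacing: float) -> tuple[float, ...]:
    near = np.unique(np.round(np.sort(near) / spacing) * spacing)
    # fold -pi onto pi
    folded = []
    for t in near:
        if abs(t + math.pi) < 2 * spacing:
            t = math.pi
        if abs(abs(t) - math.pi) < 2 * spacing:
            t = math.pi
        if abs(t) < 2 * spacing:
            t = 0.0
        folded.append(t)
    out: list[float] = []
    for t in sorted(set(folded)):
        if not out or abs(t - out[-1]) > 3 * spacing:
            out.append(t)
    return tuple(out)


def _cross_check_identity(params: Hyperparams, status: str,
                          tangencies: Iterable[float]) -> None:
    s = params.alpha + params.lam
    bounded = status in ("stable", "marginally_stable")
    if bounded != (s <= 1.0 + 1e-12):
        raise AssertionError(
            "identity-case grid classification disagrees with the closed "
            f"criterion alpha+lam<=1 (alpha+lam={s}, status={status})")
    if bounded and abs(s - 1.0) < 1e-12:
        if not any(abs(t - math.pi) < 1e-6 for t in tangencies):
            raise AssertionError("expected a tangency at pi when alpha+lam=1")


# ---------------------------------------------------------------------------
# wave modes (speed and spread at tangency points)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveMode:
    theta0: float
    speed: float
    spread: float
    oscillatory: bool


def _log_expansion(theta0: float, params: Hyperparams, gains: GainPair,
                   step: float = 1e-4) -> tuple[float, float]:
    """First/second coefficients of log(rho(theta0+t)/rho(theta0)) at t=0.

    Returns ``(speed, spread)`` with speed = -Im d/dt and spread =
    -1/2 Re d^2/dt^2, by 5-point central differences.
    """
    r0 = rho(theta0, params, gains)
    ts = np.array([-2, -1, 1, 2], dtype=float) * step

    def f(t: float) -> complex:
        return cmath.log(rho(theta0 + t, params, gains) / r0)

    fm2, fm1, fp1, fp2 = (f(t) for t in ts)
    d1 = (-fp2 + 8 * fp1 - 8 * fm1 + fm2) / (12 * step)
    d2 = (-fp2 + 16 * fp1 - 30 * 0.0 + 16 * fm1 - fm2) / (12 * step ** 2)
    return (-d1.imag, -0.5 * d2.real)


def identity_speeds(params: Hyperparams) -> dict:
    """Closed-form c0, sigma0, c_pi, sigma_pi of the identity case."""
    a, b, l = params.alpha, params.beta, params.lam
    return {
        "c0": (b + a - l) / (1 - b),
        "sigma0": (b * (1 - a - l) + a + l - (l - a) ** 2) / (2 * (1 - b) ** 2),
        "c_pi": (-b + a - l) / (1 + b),
        "sigma_pi": (1 - (a - l) ** 2) / (2 * (1 + b) ** 2),
    }


def wave_mode_at(theta0: float, params: Hyperparams,
                 gains: GainPair = GainPair.identity(),
                 tol: float = 1e-9) -> WaveMode:
    """Wave mode carried by the tangency at ``theta0`` (0 or pi).

    Closed forms are used for identity gains and always cross-checked against
    the numerical log-expansion to 1e-6; other gains use the expansion.
    """
    if not (abs(theta0) < 1e-12 or abs(theta0 - math.pi) < 1e-12):
        raise ValueError("theta0 must be 0 or pi")
    r0 = rho(theta0, params, gains)
    if abs(abs(r0) - 1.0) > tol:
        raise ModeAbsentError(
            f"mode absent: |rho({theta0:g})| = {abs(r0):.6f} != 1")
    speed, spread = _log_expansion(theta0, params, gains)
    if gains.is_identity:
        cf = identity_speeds(params)
        c_closed = cf["c0"] if theta0 == 0.0 else cf["c_pi"]
        s_closed = cf["sigma0"] if theta0 == 0.0 else cf["sigma_pi"]
        if abs(c_closed - speed) > 1e-6 or abs(s_closed - spread) > 1e-6:
            raise AssertionError(
                "closed-form speed/spread disagree with the log-expansion: "
                f"({c_closed}, {s_closed}) vs ({speed}, {spread})")
        speed, spread = c_closed, s_closed
    oscillatory = abs(theta0 - math.pi) < 1e-12
    return WaveMode(theta0=float(theta0), speed=float(speed),
                    spread=float(spread), oscillatory=oscillatory)


def wave_modes(params: Hyperparams,
               gains: GainPair = GainPair.identity(),
               tol: float = 1e-9) -> list[WaveMode]:
    """All wave modes at the canonical tangency points theta0 in {0, pi}."""
    modes = []
    for theta0 in (0.0, math.pi):
        try:
            modes.append(wave_mode_at(theta0, params, gains, tol=tol))
        except ModeAbsentError:
            continue
    return modes


# ---------------------------------------------------------------------------
# boundary curves of the symmetric / general symmetric analysis
# ---------------------------------------------------------------------------

def chi(x: float, params: Hyperparams) -> float:
    """Feedforward gain making rho_{g1,g2}(0) = 1 at feedback gain x."""
    if params.beta == 0.0:
        raise ValueError("boundary functions undefined for beta = 0")
    a, b, l = params.alpha, params.beta, params.lam
    return (a * x * x - (a + l) * x + l + b) / b


def zeta(x: float, params: Hyperparams) -> float:
    """Feedforward gain making rho_{g1,g2}(0) = -1 at feedback gain x."""
    if params.beta == 0.0:
        raise ValueError("boundary functions undefined for beta = 0")
    a, b, l = params.alpha, params.beta, params.lam
    return (-a * x * x + (a + l) * x + 2.0 - l - b) / b


def chi_zeta(x: float, params: Hyperparams, which: str) -> float:
    if which == "chi":
        return chi(x, params)
    if which == "zeta":
        return zeta(x, params)
    raise ValueError("which must be 'chi' or 'zeta'")


@dataclass(frozen=True)
class GammaBoundaries:
    gamma_plus0: float
    gamma_minus0: float
    ratio_bound: float            # (lam + beta) / alpha
    Lambda: Optional[float]       # lam(lam+beta)/(1-lam-beta), if defined


def gamma_boundaries(params: Hyperparams) -> GammaBoundaries:
    """Marginal gain boundaries of the symmetric (Rao-Ballard) case.

    ``gamma_pm0`` are the roots of rho_gamma(0) = -1; when alpha + lam = 1
    the negative root is exactly -1.  ``Lambda`` is the alpha value at which
    gamma_minus0 = -(lam+beta)/alpha, defined only for lam + beta < 1.
    """
    a, b, l = params.alpha, params.beta, params.lam
    if a == 0.0:
        raise ValueError("gamma boundaries undefined for alpha = 0")
    disc = (l + a - b) ** 2 + 4 * a * (2 - l - b)
    root = math.sqrt(disc)
    gp = (l + a - b + root) / (2 * a)
    gm = (l + a - b - root) / (2 * a)
    Lam = l * (l + b) / (1 - l - b) if l + b < 1.0 else None
    return GammaBoundaries(gamma_plus0=gp, gamma_minus0=gm,
                           ratio_bound=(l + b) / a, Lambda=Lam)


def region_of(beta: float, lam: float) -> str:
    """Five-region partition of the quadrant (beta, lam) in [0,1) x (0,1).

    Region I/II: 2*lam + beta >= 1, split on beta <= lam vs beta > lam.
    Region III/IV/V: 2*lam + beta < 1, with IV/V separated by the sign of
    beta^2 - beta(1-lam) + lam.  Boundary ties follow the defining weak and
    strict inequalities exactly.
    """
    if not (0.0 <= beta < 1.0 and 0.0 < lam < 1.0):
        raise ValueError(f"(beta, lam) = ({beta}, {lam}) outside [0,1)x(0,1)")
    if 2 * lam + beta >= 1.0:
        return "I" if beta <= lam else "II"
    if beta <= lam:
        return "III"
    parabola = beta ** 2 - beta * (1.0 - lam) + lam
    return "IV" if parabola >= 0.0 else "V"
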