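"""Delay-induced spectral machinery.

Discrete side: with a transmission delay of k steps the amplification
factor rho(theta) becomes a root of the degree-(2k+1) polynomial

    (1 - beta e^{-i theta}) rho^{2k+1} - (1 - beta - lam) rho^{2k}
        - (alpha e^{-i theta} + lam e^{i theta}) rho^k + alpha = 0,

whose theta = 0 reduction always has the root rho = 1; further unit-modulus
roots e^{i omega} are the marginal oscillation frequencies.

Continuous side (beta_t = 0): the delayed lattice ODE admits homogeneous
oscillations with a closed-form (tau, omega) pair, and traveling-wave
solutions e^{i(omega t + j theta)} governed by a reduced scalar dispersion
equation in omega with theta recovered by an arctan formula.  theta in
(0, pi) is a backward (feedback) wave, theta in (pi, 2 pi) a forward wave.
Branches of solutions in the feedback/feedforward ratio rho_ratio =
lambda_t/alpha_t emerge at rho_c, cross at rho_ratio = 1 and collide at a
fold rho_0; this module traces them with nearest-neighbor continuation and
refines the fold and the direction-flip point by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .params import Hyperparams

TWO_PI = 2.0 * math.pi
_RESID_TOL = 1e-10


# ---------------------------------------------------------------------------
# discrete delayed characteristic equation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DelayCharacteristic:
    params: Hyperparams
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("delay k must be >= 1")

    def coefficients(self, theta: float) -> np.ndarray:
        """Polynomial coefficients, highest degree first (degree 2k+1)."""
        a, b, l = self.params.as_tuple()
        em = complex(math.cos(theta), -math.sin(theta))
        ep = em.conjugate()
        c = np.zeros(2 * self.k + 2, dtype=complex)
        c[0] = 1.0 - b * em
        c[1] = -(1.0 - b - l)
        c[self.k + 1] = -(a * em + l * ep)
        c[-1] += a
        return c


def characteristic_roots(char: DelayCharacteristic, theta: float) -> np.ndarray:
    """All 2k+1 roots at spatial frequency theta (companion-matrix method).

    Roots are sorted by descending modulus, then ascending argument, and each
    residual is checked against the polynomial.
    """
    coeffs = char.coefficients(theta)
    if abs(coeffs[0]) < 1e-14:
        raise ValueError("degenerate leading coefficient (beta e^{-i theta} = 1)")
    roots = np.roots(coeffs)
    scale = np.abs(coeffs).max()
    for r in roots:
        resid = abs(np.polyval(coeffs, r))
        size = max(1.0, abs(r)) ** (2 * char.k + 1)
        if resid > 1e-8 * scale * size:
            raise AssertionError(f"root residual {resid:.2e} too large")
    order = np.lexsort((np.angle(roots), -np.abs(roots)))
    return roots[order]


def max_modulus_map(char: DelayCharacteristic, n_theta: int = 721) -> float:
    """max over theta of the largest root modulus (spectral radius map)."""
    thetas = np.linspace(-math.pi, math.pi, n_theta)
    return float(max(np.abs(characteristic_roots(char, t)).max() for t in thetas))


@dataclass(frozen=True)
class DelayedSpeeds:
    c0_k: float
    c_tilde0: Optional[float]   # secondary (oscillatory) speed, k=1 & a+b+l=1


def delayed_speeds(params: Hyperparams, k: int) -> DelayedSpeeds:
    """Closed-form wave speeds of the delayed recurrence.

    ``c0_k = (alpha+beta-lam) / (1-beta+k(lam-alpha))`` has a pole at
    k = (1-beta)/(alpha-lam) when lam < alpha.  ``c_tilde0`` is the speed of
    the oscillatory secondary wave, which exists only for k = 1 when
    alpha + beta + lam = 1 (the theta=0 root -1).
    """
    if k < 1:
        raise ValueError("delay k must be >= 1")
    a, b, l = params.as_tuple()
    den = 1.0 - b + k * (l - a)
    if abs(den) < 1e-12:
        raise ValueError(f"speed undefined at this delay (pole at k = {k})")
    c0k = (a + b - l) / den
    ct = None
    if k == 1 and abs(a + b + l - 1.0) < 1e-12:
        ct = (a + b - l) / (5.0 - 5.0 * b - a - 3.0 * l)
    return DelayedSpeeds(c0_k=c0k, c_tilde0=ct)


def marginal_frequencies(params: Hyperparams, k: int,
                         n_scan: int = 4096,
                         resid_tol: float = 1e-4) -> np.ndarray:
    """Frequencies omega in [0, 2 pi) with a unit-circle root e^{i omega}
    of the theta = 0 characteristic equation.

    Found by a dense scan of the squared residual of the two trigonometric
    equations followed by local polish; omega = 0 is always a solution.
    ``resid_tol`` bounds the accepted max-norm residual of the two
    equations: hyper-parameters quoted to a few printed digits place the
    tangency only approximately on the unit circle, so the default admits
    such near-tangencies while still rejecting spurious minima.
    """
    if k < 1:
        raise ValueError("delay k must be >= 1")
    a, b, l = params.as_tuple()

    def f1(w):
        return ((1 - b) * np.cos((2 * k + 1) * w) - (1 - b - l) * np.cos(2 * k * w)
                - (a + l) * np.cos(k * w) + a)

    def f2(w):
        return ((1 - b) * np.sin((2 * k + 1) * w) - (1 - b - l) * np.sin(2 * k * w)
                - (a + l) * np.sin(k * w))

    def resid(w):
        return f1(w) ** 2 + f2(w) ** 2

    ws = np.linspace(0.0, TWO_PI, n_scan, endpoint=False)
    rs = resid(ws)
    roots = [0.0]
    for i in range(1, n_scan - 1):
        if rs[i] <= rs[i - 1] and rs[i] <= rs[i + 1] and rs[i] < 1e-2:
            res = minimize_scalar(resid, bracket=None,
                                  bounds=(ws[i - 1], ws[i + 1]), method="bounded",
                                  options={"xatol": 1e-14})
            w = float(res.x)
            if max(abs(f1(w)), abs(f2(w))) < resid_tol and w > 1e-8:
                roots.append(w % TWO_PI)
    roots = sorted(roots)
    out: list[float] = []
    for w in roots:
        if not out or abs(w - out[-1]) > 1e-6:
            out.append(w)
    return np.array(out)


# ---------------------------------------------------------------------------
# continuous delayed model: homogeneous oscillations
# ---------------------------------------------------------------------------

def homogeneous_oscillation(rho_ratio: float, alpha_t: float,
                            branch_k: int = 1) -> Optional[tuple[float, float]]:
    """Closed-form (tau, omega) of the layer-synchronous oscillation.

    For rho_ratio = lambda_t/alpha_t in [0, 3) the delayed homogeneous ODE
    is marginally oscillatory at

        omega = alpha_t * sqrt((1 + rho)(3 - rho)),
        tau   = (-arccos((rho - 1)/2) + 2 k pi) / omega,

    the smallest positive tau being at branch k = 1.  For rho_ratio >= 3
    only omega = 0 survives and None is returned.
    """
    if alpha_t <= 0:
        raise ValueError("alpha_t must be positive")
    if branch_k < 1:
        raise ValueError("branch_k must be >= 1")
    if rho_ratio < 0:
        raise ValueError("rho_ratio must be nonnegative")
    if rho_ratio >= 3.0:
        return None
    omega = alpha_t * math.sqrt((1.0 + rho_ratio) * (3.0 - rho_ratio))
    tau = (-math.acos((rho_ratio - 1.0) / 2.0) + 2.0 * branch_k * math.pi) / omega
    return (tau, omega)


def homogeneous_residual(rho_ratio: float, alpha_t: float, tau: float,
                         omega: float) -> float:
    """Residual of the two homogeneous-oscillation equations."""
    r1 = -rho_ratio + (1 + rho_ratio) * math.cos(tau * omega) - math.cos(2 * tau * omega)
    r2 = omega / alpha_t - (-(1 + rho_ratio) * math.sin(tau * omega)
                            + math.sin(2 * tau * omega))
    return max(abs(r1), abs(r2) * alpha_t)


# ---------------------------------------------------------------------------
# continuous delayed model: oscillatory traveling waves (beta_t = 0)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TravelingWaveSolution:
    rho_ratio: float
    omega: float                # rad/ms
    theta: float                # [0, 2 pi)
    direction: str              # backward | forward | none
    branch: str                 # primary | secondary | special
    residual: float

    @property
    def freq_hz(self) -> float:
        return 1000.0 * self.omega / TWO_PI


def _direction(theta: float) -> str:
    if 1e-9 < theta < math.pi - 1e-9:
        return "backward"
    if math.pi + 1e-9 < theta < TWO_PI - 1e-9:
        return "forward"
    return "none"


def dispersion_residual(rho_ratio: float, alpha_t: float, tau: float,
                        omega: float, theta: float) -> float:
    """Residual of the full two-equation traveling-wave system."""
    lt = rho_ratio * alpha_t
    r1 = (alpha_t * (math.cos(omega * tau + theta) - math.cos(2 * omega * tau))
          + lt * (math.cos(omega * tau - theta) - 1.0))
    r2 = omega + (alpha_t * (math.sin(omega * tau + theta)
                             - math.sin(2 * omega * tau))
                  + lt * math.sin(omega * tau - theta))
    return max(abs(r1), abs(r2))


def _reduced(omega: np.ndarray, rho: float, alpha_t: float, tau: float):
    """omega - alpha_t * 2 sin(2wt)(1-rho^2) / (2 rho cos(2wt)+rho^2+1)."""
    s = np.sin(2.0 * omega * tau)
    c = np.cos(2.0 * omega * tau)
    return omega - alpha_t * 2.0 * s * (1.0 - rho ** 2) / (2.0 * rho * c
                                                           + rho ** 2 + 1.0)


def _theta_from_omega(omega: float, rho: float, tau: float) -> float:
    s = math.sin(2.0 * omega * tau)
    c = math.cos(2.0 * omega * tau)
    den = rho + c
    if abs(den) < 1e-12:
        u = math.pi / 2.0 if s > 0 else -math.pi / 2.0
    else:
        u = math.atan(s / den)
    return (omega * tau - 2.0 * u) % TWO_PI


def solve_traveling_waves(rho_ratio: float, alpha_t: float, tau: float,
                          n_scan: int = 4000) -> list[TravelingWaveSolution]:
    """All nontrivial traveling-wave solutions (omega > 0) at one rho_ratio.

    Implements the analytical case split: rho_ratio = 0 reduces to
    omega = 2 alpha_t sin(2 omega tau) with theta = -3 omega tau mod 2 pi
    (nontrivial roots only when 4 alpha_t tau > 1); rho_ratio = 1 has the
    closed form omega = pi/(2 tau) with two symmetric theta values when
    4 alpha_t tau >= pi; the general case brackets the roots of the reduced
    scalar equation on (0, pi/tau) and recovers theta from the arctan
    formula.  Every solution carries the residual of the full two-equation
    system.  The empty list is a valid outcome (only the trivial
    omega = theta = 0 solution exists).
    """
    if alpha_t <= 0 or tau <= 0:
        raise ValueError("alpha_t and tau must be positive")
    if rho_ratio < 0:
        raise ValueError("rho_ratio must be nonnegative")
    sols: list[TravelingWaveSolution] = []

    def make(omega: float, theta: float, branch: str) -> TravelingWaveSolution:
        theta %= TWO_PI
        resid = dispersion_residual(rho_ratio, alpha_t, tau, omega, theta)
        if resid > _RESID_TOL * max(1.0, alpha_t):
            raise AssertionError(
                f"dispersion residual {resid:.2e} at (omega, theta) = "
                f"({omega:.6f}, {theta:.6f})")
        return TravelingWaveSolution(rho_ratio=rho_ratio, omega=omega,
                                     theta=theta, direction=_direction(theta),
                                     branch=branch, residual=resid)

    if abs(rho_ratio - 1.0) < 1e-12:
        if 4.0 * alpha_t * tau < math.pi:
            return []
        omega = math.pi / (2.0 * tau)
        th = math.acos(-math.pi / (4.0 * alpha_t * tau))
        return [make(omega, th, "primary"), make(omega, TWO_PI - th, "secondary")]

    if rho_ratio == 0.0:
        def g(w):
            return w - 2.0 * alpha_t * np.sin(2.0 * w * tau)
        roots = _bracketed_roots(g, tau, n_scan)
        return [make(w, -3.0 * w * tau, "primary") for w in roots]

    def g(w):
        return _reduced(np.asarray(w), rho_ratio, alpha_t, tau)

    roots = _bracketed_roots(g, tau, n_scan)
    out = []
    for w in roots:
        th = _theta_from_omega(w, rho_ratio, tau)
        branch = "special" if abs(rho_ratio + math.cos(2 * w * tau)) < 1e-9 \
            else "primary"
        out.append(make(w, th, branch))
    # heuristic branch labels when two roots coexist: the branches cross at
    # rho_ratio = 1, so the primary (continued from rho_ratio = 0) is the
    # larger omega below the crossing and the smaller omega above it
    if len(out) == 2:
        hi, lo = sorted(out, key=lambda s: -s.omega)
        if rho_ratio < 1.0:
            prim, sec = hi, lo
        else:
            prim, sec = lo, hi
        out = [TravelingWaveSolution(**{**prim.__dict__, "branch": "primary"}),
               TravelingWaveSolution(**{**sec.__dict__, "branch": "secondary"})]
    return out


def _bracketed_roots(g, tau: float, n_scan: int,
                     w_max: Optional[float] = None) -> list[float]:
    """Positive roots of g on (0, pi/tau) by scan + bisection."""
    w_max = w_max or math.pi / tau
    ws = np.linspace(0.0, w_max, n_scan + 1)[1:]
    vals = np.asarray(g(ws), dtype=float)
    roots: list[float] = []
    for i in range(len(ws) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(ws[i]))
        elif a * b < 0.0:
            roots.append(float(brentq(lambda w: float(g(np.asarray(w))),
                                      ws[i], ws[i + 1], xtol=1e-12)))
    merged: list[float] = []
    for r in sorted(roots):
        if r > 1e-10 and (not merged or abs(r - merged[-1]) > 1e-8):
            merged.append(r)
    return merged


# ---------------------------------------------------------------------------
# branch continuation in rho_ratio
# ---------------------------------------------------------------------------

@dataclass
class BranchTrace:
    samples: list[TravelingWaveSolution]
    primary: list[TravelingWaveSolution]
    secondary: list[TravelingWaveSolution]
    rho_c: float                      # analytic emergence threshold
    rho_c_detected: Optional[float]   # first grid point with a second root
    rho_0: Optional[float]            # fold where the branches collide
    flip_rho: Optional[float] = None  # theta = pi crossing on the secondary
    alpha_t: float = 0.0
    tau: float = 0.0


def emergence_threshold(alpha_t: float, tau: float) -> float:
    """rho_c = (4 a t - 1)/(4 a t + 1): the secondary branch exists for
    rho_ratio > rho_c, equivalent to 4 alpha_t tau > (1+rho)/(1-rho)."""
    x = 4.0 * alpha_t * tau
    return (x - 1.0) / (x + 1.0)


def _count_roots(rho: float, alpha_t: float, tau: float,
                 n_scan: int = 4000) -> int:
    return len(solve_traveling_waves(rho, alpha_t, tau, n_scan=n_scan))


def trace_branches(alpha_t: float, tau: float,
                   rho_grid: np.ndarray) -> BranchTrace:
    """Continue the two traveling-wave branches over a rho_ratio grid.

    Solutions at consecutive grid points are matched by nearest neighbors in
    (omega * tau, theta); the theta distance disambiguates the omega
    crossing at rho_ratio = 1.  The fold rho_0 (both branches vanish) is
    bisected to 1e-6, as is the secondary branch's theta = pi crossing when
    it occurs inside the grid.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    if rho_grid[0] != 0.0 or np.any(np.diff(rho_grid) <= 0):
        raise ValueError("rho_grid must be ascending and start at 0")
    if np.max(np.diff(rho_grid)) > 0.05:
        raise ValueError("rho grid too coarse for branch matching (step > 0.05)")

    samples: list[TravelingWaveSolution] = []
    primary: list[TravelingWaveSolution] = []
    secondary: list[TravelingWaveSolution] = []
    rho_c_detected = None
    last_with_roots = None
    first_without = None

    def key(s: TravelingWaveSolution) -> np.ndarray:
        return np.array([s.omega * tau, s.theta])

    for rho in rho_grid:
        sols = solve_traveling_waves(float(rho), alpha_t, tau)
        samples.extend(sols)
        if sols:
            last_with_roots = float(rho)
        elif last_with_roots is not None and first_without is None:
            first_without = float(rho)
        if len(sols) >= 2 and rho_c_detected is None:
            rho_c_detected = float(rho)
        # nearest-neighbor matching against current branch tips
        pool = list(sols)
        if primary and pool:
            i = int(np.argmin([np.linalg.norm(key(s) - key(primary[-1]))
                               for s in pool]))
            primary.append(pool.pop(i))
        elif not primary and pool:
            # the unique rho_ratio = 0 root seeds the primary branch
            primary.append(pool.pop(int(np.argmax([s.omega for s in pool]))))
        if pool:
            if secondary:
                i = int(np.argmin([np.linalg.norm(key(s) - key(secondary[-1]))
                                   for s in pool]))
                secondary.append(pool.pop(i))
            else:
                secondary.append(pool.pop(0))

    rho_0 = None
    if last_with_roots is not None and first_without is not None:
        lo, hi = last_with_roots, first_without
        while hi - lo > 1e-6:
            mid = 0.5 * (lo + hi)
            if _count_roots(mid, alpha_t, tau) > 0:
                lo = mid
            else:
                hi = mid
        rho_0 = 0.5 * (lo + hi)

    flip = _locate_flip(secondary, alpha_t, tau)
    return BranchTrace(samples=samples, primary=primary, secondary=secondary,
                       rho_c=emergence_threshold(alpha_t, tau),
                       rho_c_detected=rho_c_detected, rho_0=rho_0,
                       flip_rho=flip, alpha_t=alpha_t, tau=tau)


def _secondary_theta(rho: float, alpha_t: float, tau: float) -> Optional[float]:
    sols = solve_traveling_waves(rho, alpha_t, tau)
    for s in sols:
        if s.branch == "secondary":
            return s.theta
    return None


def _locate_flip(secondary: list[TravelingWaveSolution], alpha_t: float,
                 tau: float) -> Optional[float]:
    """Bisect the rho at which the secondary branch's theta crosses pi."""
    for prev, cur in zip(secondary, secondary[1:]):
        if (prev.theta - math.pi) * (cur.theta - math.pi) < 0:
            lo, hi = prev.rho_ratio, cur.rho_ratio
            s_lo = _secondary_theta(lo, alpha_t, tau)
            if s_lo is None:
                return None
            sign_lo = s_lo - math.pi
            while hi - lo > 1e-6:
                mid = 0.5 * (lo + hi)
                th = _secondary_theta(mid, alpha_t, tau)
                if th is None:
                    return None
                if (th - math.pi) * sign_lo > 0:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)
    return None
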