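"""Exact discrete-time simulators for the predictive-coding lattice.

The interior update (per neural assembly with gains ``(g1, g2)``) is

    e_j^{n+1} - beta*g1*e_{j-1}^{n+1} =
        alpha*g2*e_{j-1}^n + (1 - beta - lam - alpha*g2^2)*e_j^n
        + lam*g2*e_{j+1}^n,

an implicit recurrence whose left coupling is strictly lower triangular in
``j``; every step is resolved exactly by one left-to-right forward sweep
(a first-order linear filter), never by matrix inversion.

Infinite-lattice runs are truncated to a window sized from the closed-form
wave speed and spread; a certificate asserts after the run that the
truncation edges stayed numerically silent, so the window behaved like the
infinite lattice.  Semi-infinite runs impose the source at layer 0 and the
no-feedback top-boundary rule at the truncation layer, which is the model's
own physical boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .amplification import _log_expansion, rho
from .fields import SpaceTimeField
from .params import GainPair, Hyperparams

_EDGE_TOL = 1e-13


class TruncationError(RuntimeError):
    """The truncated window was too small for the requested run."""


class CompatibilityError(ValueError):
    """Source and initial data disagree at (n, j) = (0, 0)."""


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sweep(rhs: np.ndarray, bg1: float, left_in: float = 0.0) -> np.ndarray:
    """Solve y[j] - bg1*y[j-1] = rhs[j] left to right (y[-1] = left_in)."""
    if bg1 == 0.0:
        return rhs.copy()
    y, _ = lfilter([1.0], [1.0, -bg1], rhs, zi=np.array([bg1 * left_in]))
    return y


def _shift_right(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    out[0] = 0.0
    out[1:] = x[:-1]
    return out


def _shift_left(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    out[-1] = 0.0
    out[:-1] = x[1:]
    return out


def drift_and_spread(params: Hyperparams, gains: GainPair) -> tuple[float, float]:
    """Drift/spread estimate used to size truncation windows.

    Uses the log-expansion of rho at theta = 0 when it is meaningful and a
    conservative fallback otherwise.
    """
    try:
        c, s = _log_expansion(0.0, params, gains)
        if not (math.isfinite(c) and math.isfinite(s)):
            raise ValueError
        return c, max(abs(s), 0.05)
    except Exception:
        return 2.0, 1.0


def _window(j_min: int, j_max: int, n_steps: int, params: Hyperparams,
            gains: GainPair) -> tuple[int, int]:
    c0, s0 = drift_and_spread(params, gains)
    right = int(math.ceil(max(1.0, c0 + 6.0 * s0 + 1.0))) * max(n_steps, 1) + 8
    # the implicit sweep leaks a beta^j tail rightward every step; make sure
    # that tail alone has decayed below the certificate tolerance at the edge
    bg = abs(params.beta * gains.gamma_f)
    if 0.0 < bg < 1.0:
        right += int(math.ceil(math.log(1e-15) / math.log(bg)))
    left = n_steps + 8
    return j_min - left, j_max + right


def _certify(field: SpaceTimeField) -> None:
    if field.edge_magnitude() > _EDGE_TOL:
        raise TruncationError(
            "domain too small: truncation-edge magnitude "
            f"{field.edge_magnitude():.2e} exceeds {_EDGE_TOL:.0e}")


def _support(values: np.ndarray) -> tuple[int, int]:
    nz = np.nonzero(values)[0]
    if nz.size == 0:
        return 0, 0
    return int(nz[0]), int(nz[-1])


# ---------------------------------------------------------------------------
# scalar lattice
# ---------------------------------------------------------------------------

def simulate_lattice(initial: np.ndarray,
                     params: Hyperparams,
                     gains: GainPair = GainPair.identity(),
                     n_steps: int = 1,
                     domain: str = "infinite_truncated",
                     source=None,
                     j_initial: int = 0,
                     certify: bool = True) -> SpaceTimeField:
    """Exact iterates of the scalar (per-assembly) recurrence.

    Parameters
    ----------
    initial
        Initial layer sequence; entry ``i`` is layer ``j_initial + i``.
        For a semi-infinite run ``j_initial`` must be 0 and ``initial[0]``
        must match the source at step 0.
    source
        Required for ``domain="semi_infinite"``: scalar (constant source) or
        a sequence of length ``n_steps + 1``.
    """
    gains.check_pole(params)
    initial = np.asarray(initial, dtype=float)
    if initial.ndim != 1:
        raise ValueError("initial must be one-dimensional")
    a, b, l = params.alpha, params.beta, params.lam
    g1, g2 = gains.gamma_f, gains.gamma_b
    bg1 = b * g1
    c_mid = 1.0 - b - l - a * g2 * g2

    if domain == "infinite_truncated":
        lo, hi = _support(initial)
        jlo, jhi = _window(j_initial + lo, j_initial + hi, n_steps, params, gains)
        J = jhi - jlo + 1
        values = np.zeros((n_steps + 1, J))
        values[0, j_initial + lo - jlo:j_initial + hi - jlo + 1] = initial[lo:hi + 1]
        for n in range(n_steps):
            prev = values[n]
            rhs = (a * g2 * _shift_right(prev) + c_mid * prev
                   + l * g2 * _shift_left(prev))
            values[n + 1] = _sweep(rhs, bg1)
        field = SpaceTimeField(values, j_offset=jlo, domain=domain)
        if certify:
            _certify(field)
        return field

    if domain == "semi_infinite":
        if source is None:
            raise ValueError("semi_infinite runs require a source term")
        if j_initial != 0:
            raise ValueError("semi_infinite initial data must start at j = 0")
        src = np.asarray(source, dtype=float)
        if src.ndim == 0:
            src = np.full(n_steps + 1, float(src))
        if src.shape != (n_steps + 1,):
            raise ValueError("source must be scalar or length n_steps + 1")
        if abs(src[0] - initial[0]) > 1e-12:
            raise CompatibilityError(
                f"compatibility violated: s_0^0 = {src[0]} != h_0 = {initial[0]}")
        _, hi = _support(initial)
        _, jhi = _window(0, hi, n_steps, params, gains)
        J = jhi + 1                      # layers 0 .. J (top boundary at J)
        values = np.zeros((n_steps + 1, J + 1))
        values[0, :initial.size] = initial
        values[0, 0] = src[0]
        for n in range(n_steps):
            prev = values[n]
            cur = np.empty_like(prev)
            cur[0] = src[n + 1]
            rhs = (a * g2 * prev[:-2] + c_mid * prev[1:-1] + l * g2 * prev[2:])
            cur[1:-1] = _sweep(rhs, bg1, left_in=cur[0])
            cur[-1] = (bg1 * cur[-2] + a * g2 * prev[-2]
                       + (1.0 - b - a * g2 * g2) * prev[-1])
            values[n + 1] = cur
        field = SpaceTimeField(values, j_offset=0, domain=domain)
        if certify:
            _certify(field)
        return field

    raise ValueError(f"unknown domain {domain!r}")


# ---------------------------------------------------------------------------
# full matrix model on a finite network
# ---------------------------------------------------------------------------

def simulate_matrix(initial: np.ndarray,
                    Wf: np.ndarray,
                    Wb: np.ndarray,
                    params: Hyperparams,
                    source,
                    n_steps: int) -> SpaceTimeField:
    """Iterate the d-channel model on the finite network j = 0..J.

    ``initial`` has shape ``(J + 1, d)`` (layers first).  Layer 0 is pinned
    to the source, layers 1..J-1 follow the interior recurrence, and the top
    layer J uses the no-feedback boundary rule.  The implicit feedforward
    coupling ``beta * Wf`` is resolved by a forward sweep in ``j``.
    """
    initial = np.asarray(initial, dtype=float)
    Wf = np.asarray(Wf, dtype=float)
    Wb = np.asarray(Wb, dtype=float)
    if initial.ndim != 2:
        raise ValueError("initial must have shape (J + 1, d)")
    J = initial.shape[0] - 1
    d = initial.shape[1]
    if Wf.shape != (d, d) or Wb.shape != (d, d):
        raise ValueError(f"Wf and Wb must be {d}x{d} to match the state")
    if not (np.all(np.isfinite(Wf)) and np.all(np.isfinite(Wb))
            and np.all(np.isfinite(initial))):
        raise ValueError("non-finite entries in weights or initial state")

    a, b, l = params.alpha, params.beta, params.lam
    src = np.asarray(source, dtype=float)
    if src.ndim == 1:
        src = np.tile(src, (n_steps + 1, 1))
    if src.shape != (n_steps + 1, d):
        raise ValueError("source must have shape (d,) or (n_steps + 1, d)")
    if not np.allclose(src[0], initial[0], atol=1e-12, rtol=0):
        raise CompatibilityError("compatibility violated: S_0^0 != H_0")

    I = np.eye(d)
    M_back = a * Wb.T                                 # acts on E_{j-1}^n
    M_mid = (1.0 - b - l) * I - a * (Wb.T @ Wb)       # interior memory term
    M_up = l * Wb                                     # acts on E_{j+1}^n
    M_mid_top = (1.0 - b) * I - a * (Wb.T @ Wb)       # top layer, no feedback
    F = b * Wf                                        # implicit coupling

    values = np.zeros((n_steps + 1, J + 1, d))
    values[0] = initial
    for n in range(n_steps):
        prev = values[n]
        cur = np.empty_like(prev)
        cur[0] = src[n + 1]
        for j in range(1, J):
            cur[j] = (F @ cur[j - 1] + M_back @ prev[j - 1]
                      + M_mid @ prev[j] + M_up @ prev[j + 1])
        cur[J] = F @ cur[J - 1] + M_back @ prev[J - 1] + M_mid_top @ prev[J]
        values[n + 1] = cur
    return SpaceTimeField(values, j_offset=0, domain="semi_infinite")


# ---------------------------------------------------------------------------
# fundamental solution and superposition
# ---------------------------------------------------------------------------

def fundamental_solution(params: Hyperparams,
                         gains: GainPair = GainPair.identity(),
                         n: int = 1) -> SpaceTimeField:
    """Dirac-initialized trajectory G^0..G^n on the (truncated) infinite lattice."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return simulate_lattice(np.array([1.0]), params, gains, n_steps=n,
                            domain="infinite_truncated", j_initial=0)


def fundamental_solution_fourier(params: Hyperparams, gains: GainPair,
                                 n: int, js: np.ndarray,
                                 n_quad: int = 8192) -> np.ndarray:
    """Inverse-Fourier quadrature of rho(theta)^n -- independent route to G_j^n.

    The integrand is smooth and 2*pi periodic, so the trapezoid rule
    converges spectrally.
    """
    th = np.linspace(-math.pi, math.pi, n_quad, endpoint=False)
    r = rho(th, params, gains) ** n
    js = np.asarray(js)
    phases = np.exp(1j * np.outer(js, th))
    return (phases * r).mean(axis=1).real


def superpose(G: SpaceTimeField, initial: np.ndarray,
              j_initial: int = 0) -> SpaceTimeField:
    """Convolve the fundamental solution with an initial sequence.

    Returns the field ``e_j^n = sum_l G_{j-l}^n h_l`` which equals direct
    simulation started from ``initial``.
    """
    initial = np.asarray(initial, dtype=float)
    if not np.all(np.isfinite(initial)):
        raise ValueError("initial sequence must be finite")
    T = G.values.shape[0]
    J = G.n_layers + initial.size - 1
    values = np.zeros((T, J))
    g = G.scalar
    for n in range(T):
        values[n] = np.convolve(g[n], initial)
    return SpaceTimeField(values, j_offset=G.j_offset + j_initial,
                          domain="infinite_truncated")


# ---------------------------------------------------------------------------
# transmission delays
# ---------------------------------------------------------------------------

@dataclass
class DelayHistory:
    """The 2k+1 initial layer sequences of the delayed model, oldest first."""

    buffer: np.ndarray          # shape (2k+1, J)
    j_offset: int = 0

    def __post_init__(self) -> None:
        self.buffer = np.atleast_2d(np.asarray(self.buffer, dtype=float))
        if self.buffer.shape[0] % 2 != 1:
            raise ValueError("history depth must be odd (2k + 1)")

    @property
    def k(self) -> int:
        return (self.buffer.shape[0] - 1) // 2

    @classmethod
    def dirac(cls, k: int, direction: np.ndarray | None = None,
              j: int = 0) -> "DelayHistory":
        """History concentrated at layer ``j`` along a temporal direction.

        ``direction`` is the (2k+1)-vector of values across the history
        steps; default is the constant history (1, ..., 1).
        """
        depth = 2 * k + 1
        if direction is None:
            direction = np.ones(depth)
        direction = np.asarray(direction, dtype=float)
        if direction.shape != (depth,):
            raise ValueError(f"direction must have length {depth}")
        return cls(direction[:, None].copy(), j_offset=j)


def delayed_drift(params: Hyperparams, k: int) -> float:
    a, b, l = params.alpha, params.beta, params.lam
    den = 1.0 - b + k * (l - a)
    if abs(den) < 1e-12:
        return 2.0
    return (a + b - l) / den


def simulate_delayed(history: DelayHistory,
                     params: Hyperparams,
                     k: int,
                     n_steps: int,
                     mode: str = "direct",
                     certify: bool = True) -> SpaceTimeField:
    """Iterate the delayed recurrence (delay of k steps on the error terms).

    ``mode="direct"`` iterates the scalar equation with its 2k+1-deep
    history; ``mode="companion"`` rewrites the run as a first-order
    recurrence on the history vector E_j^n = (e_j^{n-2k}, ..., e_j^n) with
    companion matrices Q_0, Q_{+/-1}.  Both modes agree exactly; k = 0
    reduces to the non-delayed lattice.

    The returned field stacks the 2k+1 history rows first, so row ``t`` is
    ``e^t`` for t = 0 .. 2k + n_steps.
    """
    if k < 0:
        raise ValueError("delay k must be nonnegative")
    if history.k != k:
        raise ValueError(f"history depth {history.buffer.shape[0]} "
                         f"does not match 2k+1 = {2 * k + 1}")
    if mode not in ("direct", "companion"):
        raise ValueError("mode must be 'direct' or 'companion'")
    a, b, l = params.alpha, params.beta, params.lam
    depth = 2 * k + 1

    nz = np.nonzero(np.any(history.buffer != 0.0, axis=0))[0]
    lo = int(nz[0]) if nz.size else 0
    hi = int(nz[-1]) if nz.size else 0
    c0 = delayed_drift(params, max(k, 1))
    right = int(math.ceil(max(1.0, abs(c0) + 2.0))) * max(n_steps, 1) + 8
    left = n_steps + 8
    jlo = history.j_offset + lo - left
    jhi = history.j_offset + hi + right
    J = jhi - jlo + 1

    values = np.zeros((depth + n_steps, J))
    sl = history.j_offset - jlo
    values[:depth, sl + lo:sl + hi + 1] = history.buffer[:, lo:hi + 1]

    if k == 0:
        base = simulate_lattice(values[0], params, GainPair.identity(),
                                n_steps=n_steps, j_initial=jlo, certify=False)
        field = SpaceTimeField(base.values, j_offset=base.j_offset,
                               domain="infinite_truncated")
        if certify:
            _certify(field)
        return field

    if mode == "direct":
        for t in range(depth - 1, depth + n_steps - 1):
            e_n = values[t]
            e_nk = values[t - k]
            e_n2k = values[t - 2 * k]
            rhs = (a * _shift_right(e_nk) + (1.0 - b - l) * e_n
                   - a * e_n2k + l * _shift_left(e_nk))
            values[t + 1] = _sweep(rhs, b)
    else:
        Q0, Q1, Qm1 = companion_matrices(params, k)
        assert Qm1[-1, -1] == 1.0 and np.count_nonzero(Qm1) == 1
        state = values[:depth].copy()          # (depth, J): E_j^{2k} columns
        for t in range(n_steps):
            q1s = Q1 @ state
            expl = Q0 @ state
            expl[:, 1:] += a * q1s[:, :-1]     # alpha * Q_1 E_{j-1}^n
            expl[:, :-1] += l * q1s[:, 1:]     # lam   * Q_1 E_{j+1}^n
            # implicit part beta*Q_{-1} E_{j-1}^{n+1} touches only the last
            # component, so the sweep runs on that single row
            new = expl
            new[-1] = _sweep(expl[-1], b)
            # rows of E^{n+1} are (e^{n+1-2k}, ..., e^{n+1}); newest row out
            values[depth + t] = new[-1]
            state = new
    field = SpaceTimeField(values, j_offset=jlo, domain="infinite_truncated")
    field.meta["k_delay"] = k
    if certify:
        _certify(field)
    return field


def companion_matrices(params: Hyperparams, k: int):
    """The (2k+1)-square companion matrices of the delayed recurrence.

    ``Q_0`` has ones on the superdiagonal and last row
    ``(-alpha, 0, ..., 0, 1 - beta - lam)``; ``Q_{-1}`` and ``Q_{+1}`` have a
    single nonzero unit entry on the last row, at columns 2k+1 and k+1.
    """
    depth = 2 * k + 1
    a, b, l = params.alpha, params.beta, params.lam
    Q0 = np.diag(np.ones(depth - 1), 1)
    Q0[-1, 0] = -a
    Q0[-1, -1] = 1.0 - b - l
    Q1 = np.zeros((depth, depth))
    Q1[-1, k] = 1.0
    Qm1 = np.zeros((depth, depth))
    Qm1[-1, -1] = 1.0
    return Q0, Q1, Qm1
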