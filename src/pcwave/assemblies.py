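"""Neural-assembly decomposition of symmetric commuting connectivity.

When the feedforward and feedback weight matrices are symmetric and commute
they are jointly diagonalizable in an orthonormal basis ``P``; the columns of
``P`` are the *neural assemblies*, and in that basis the d-channel model
decouples into d scalar lattices with per-assembly gains
``(gamma_p^f, gamma_p^b)``.

The module also builds the two canonical connectivity families used for
concrete experiments: residual discrete-Laplacian matrices
``zeta*I + xi*A`` (Dirichlet or periodic), and the periodic ring model of
orientation-tuned channels whose feedback matrix is local excitation with
lateral inhibition, ``Wb = I/2 - A_per/4``, and whose feedforward matrix is
chi-matched so that every assembly is marginally stable with its own wave
speed -- the mechanism behind the ring's coarse-to-fine filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import erf

from .amplification import _log_expansion, chi, rho
from .fields import SpaceTimeField
from .lattice import simulate_lattice
from .params import GainPair, Hyperparams

_COMMUTE_TOL = 1e-8


class DecompositionError(ValueError):
    """Matrices are not jointly diagonalizable to the requested tolerance."""


def save_matrix(W: np.ndarray, path) -> None:
    """Write a square matrix as delimited text with a `# d=<n>` header."""
    W = np.asarray(W, dtype=float)
    np.savetxt(path, W, header=f"d={W.shape[0]}", comments="# ")


def load_matrix(path) -> np.ndarray:
    """Read a matrix written by :func:`save_matrix`, checking the header."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# d="):
            raise ValueError(f"{path}: expected a '# d=<n>' header")
        d = int(first[4:])
        W = np.loadtxt(fh)
    W = np.atleast_2d(W)
    if W.shape != (d, d):
        raise ValueError(f"{path}: header says d={d}, data is {W.shape}")
    return W


@dataclass(frozen=True)
class AssemblyBasis:
    P: np.ndarray
    gains_f: np.ndarray
    gains_b: np.ndarray

    @property
    def d(self) -> int:
        return self.P.shape[0]

    def gain_pair(self, p: int) -> GainPair:
        return GainPair(float(self.gains_f[p]), float(self.gains_b[p]))


def _fix_signs(P: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    P = P.copy()
    for p in range(P.shape[1]):
        col = P[:, p]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if nz.size and col[nz[0]] < 0:
            P[:, p] = -col
    return P


def decompose_pair(Wf: np.ndarray, Wb: np.ndarray,
                   tol: float = _COMMUTE_TOL) -> AssemblyBasis:
    """Jointly diagonalize a symmetric commuting pair.

    Eigenpairs are ordered by ascending feedback gain, with degenerate
    feedback eigenspaces resolved by diagonalizing the projected feedforward
    matrix (ascending feedforward gain inside each block); the sign of each
    column is fixed by making its first nonzero component positive.
    """
    Wf = np.asarray(Wf, dtype=float)
    Wb = np.asarray(Wb, dtype=float)
    d = Wf.shape[0]
    if Wf.shape != (d, d) or Wb.shape != (d, d):
        raise ValueError("Wf and Wb must be square with matching size")
    scale_f = max(1.0, np.abs(Wf).max())
    scale_b = max(1.0, np.abs(Wb).max())
    if np.abs(Wf - Wf.T).max() > tol * scale_f:
        raise DecompositionError("not jointly diagonalizable: Wf asymmetric")
    if np.abs(Wb - Wb.T).max() > tol * scale_b:
        raise DecompositionError("not jointly diagonalizable: Wb asymmetric")
    if np.abs(Wf @ Wb - Wb @ Wf).max() > tol * scale_f * scale_b:
        raise DecompositionError("not jointly diagonalizable: matrices do not commute")

    wb, V = np.linalg.eigh(Wb)
    # rotate inside (near-)degenerate feedback eigenspaces so Wf is diagonal too
    P = V.copy()
    group_tol = max(tol, 1e-10) * scale_b * 10
    start = 0
    while start < d:
        stop = start + 1
        while stop < d and wb[stop] - wb[start] <= group_tol:
            stop += 1
        if stop - start > 1:
            block = P[:, start:stop]
            sub = block.T @ Wf @ block
            wsub, R = np.linalg.eigh((sub + sub.T) / 2)
            P[:, start:stop] = block @ R
        start = stop
    P = _fix_signs(P)
    gains_b = np.einsum("ip,ij,jp->p", P, Wb, P)
    gains_f = np.einsum("ip,ij,jp->p", P, Wf, P)
    off_f = P.T @ Wf @ P - np.diag(gains_f)
    if np.abs(off_f).max() > 1e-8 * scale_f:
        raise DecompositionError(
            "not jointly diagonalizable: residual off-diagonal "
            f"{np.abs(off_f).max():.2e} in the transformed Wf")
    return AssemblyBasis(P=P, gains_f=gains_f, gains_b=gains_b)


def transform(field: SpaceTimeField, basis: AssemblyBasis,
              direction: str = "to_assemblies") -> SpaceTimeField:
    """Apply the orthogonal basis change channel-wise.

    ``to_assemblies`` maps neuron coordinates E to assembly coordinates
    U = P^t E; ``from_assemblies`` maps back.  The round trip is the
    identity and channel-wise energy is preserved at every (n, j).
    """
    if field.channel_dim != basis.d:
        raise ValueError(f"field has {field.channel_dim} channels, "
                         f"basis expects {basis.d}")
    if direction == "to_assemblies":
        new = field.values @ basis.P
    elif direction == "from_assemblies":
        new = field.values @ basis.P.T
    else:
        raise ValueError("direction must be 'to_assemblies' or 'from_assemblies'")
    return replace(field, values=new, meta=dict(field.meta))


# ---------------------------------------------------------------------------
# residual discrete-Laplacian connectivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvResidual:
    W: np.ndarray
    A: np.ndarray
    spectrum_A: np.ndarray
    spectrum_W: np.ndarray
    zeta_star: Optional[float]   # Dirichlet normalization mapping extremes to -+1
    xi_star: Optional[float]


def laplacian_matrix(d: int, kind: str = "dirichlet") -> np.ndarray:
    A = -2.0 * np.eye(d) + np.diag(np.ones(d - 1), 1) + np.diag(np.ones(d - 1), -1)
    if kind == "periodic":
        A[0, -1] = 1.0
        A[-1, 0] = 1.0
    elif kind != "dirichlet":
        raise ValueError("kind must be 'dirichlet' or 'periodic'")
    return A


def periodic_laplacian_spectrum(d: int) -> np.ndarray:
    """Eigenvalues of the periodic Laplacian, with multiplicity, ordered to
    match the ring eigenvector convention (constant mode first, alternating
    mode last for even d)."""
    m, rem = divmod(d, 2)
    lam_p = [-4.0 * math.sin(p * math.pi / d) ** 2 for p in range(1, m + (rem == 1))]
    spec = [0.0]
    for lp in lam_p:
        spec += [lp, lp]
    if rem == 0:
        spec.append(-4.0)
    return np.array(spec)


def build_conv_residual(d: int, zeta: float, xi: float,
                        kind: str = "dirichlet") -> ConvResidual:
    """Build ``W = zeta*I + xi*A`` with its closed-form spectrum.

    For the Dirichlet Laplacian the spectrum of A is
    ``-4 sin^2(p pi / (2(d+1)))``, p = 1..d, and the returned
    ``(zeta_star, xi_star)`` map the extreme eigenvalues of W onto -1 and +1.
    """
    if d < 2:
        raise ValueError("d must be at least 2")
    A = laplacian_matrix(d, kind)
    if kind == "dirichlet":
        p = np.arange(1, d + 1)
        spec_A = -4.0 * np.sin(p * math.pi / (2 * (d + 1))) ** 2
        s_min = math.sin(d * math.pi / (2 * (d + 1))) ** 2
        s_max = math.sin(math.pi / (2 * (d + 1))) ** 2
        zs = (s_min + s_max) / (s_min - s_max)
        xs = 1.0 / (2.0 * (s_min - s_max))
        zeta_star, xi_star = float(zs), float(xs)
    else:
        spec_A = periodic_laplacian_spectrum(d)
        zeta_star = xi_star = None
    W = zeta * np.eye(d) + xi * A
    return ConvResidual(W=W, A=A, spectrum_A=spec_A,
                        spectrum_W=zeta + xi * spec_A,
                        zeta_star=zeta_star, xi_star=xi_star)


# ---------------------------------------------------------------------------
# ring model of orientations
# ---------------------------------------------------------------------------

def ring_eigenvectors(d: int) -> np.ndarray:
    """Explicit cosine/sine eigenbasis of the periodic Laplacian (even d).

    Column ordering follows the analytical convention: U_1 constant,
    (U_{2p}, U_{2p+1}) the cos/sin pair of spatial frequency p, U_d the
    alternating mode.  Component k (k = 1..d) of U_{2p} is cos(2kp pi/d).
    Using the printed formulas (rather than a numerical eigensolver) pins
    down the degenerate cos/sin planes and keeps mode indices reproducible.
    """
    if d % 2 != 0 or d < 4:
        raise ValueError("ring model requires even d >= 4")
    m = d // 2
    k = np.arange(1, d + 1)
    cols = [np.ones(d) / math.sqrt(d)]
    for p in range(1, m):
        c = np.cos(2 * k * p * math.pi / d)
        s = np.sin(2 * k * p * math.pi / d)
        cols.append(c / np.linalg.norm(c))
        cols.append(s / np.linalg.norm(s))
    alt = (-1.0) ** k
    cols.append(alt / np.linalg.norm(alt))
    return np.column_stack(cols)


@dataclass(frozen=True)
class RingModel:
    d: int
    Wb: np.ndarray
    Wf: np.ndarray
    P: np.ndarray
    gains_b: np.ndarray      # diagonal of D^b: 1/2 ... 3/2
    gains_f: np.ndarray      # chi(D^b)
    speeds: np.ndarray       # c_0^p per assembly
    spreads: np.ndarray      # sigma_0^p per assembly
    params: Hyperparams

    def basis(self) -> AssemblyBasis:
        return AssemblyBasis(P=self.P, gains_f=self.gains_f, gains_b=self.gains_b)

    def gain_pair(self, p: int) -> GainPair:
        return GainPair(float(self.gains_f[p]), float(self.gains_b[p]))


def ring_sigma0(params: Hyperparams, gamma: float) -> float:
    """Printed closed form of the spread sigma_0^p of a chi-matched assembly."""
    a, b, l = params.alpha, params.beta, params.lam
    cg = chi(gamma, params)
    num = (a * (1 + 4 * l) * gamma ** 2 + b + l
           - (a + l) * gamma * (a * gamma ** 2 + b + l))
    return num / (2.0 * (1.0 - b * cg) ** 2)


def build_ring_model(d: int, params: Hyperparams) -> RingModel:
    """Assemble the orientation ring: Wb = I/2 - A_per/4, Wf = chi-matched.

    The feedback gains are 1/2 + sin^2(p pi / d) (from 1/2 up to 3/2);
    applying chi to them makes every assembly marginally stable with
    rho_p(0) = 1, so each assembly carries a front with speed c_0^p.  The
    closed-form speeds/spreads are cross-checked against the numerical
    log-expansion of rho to 1e-6 and the build fails on a mismatch.
    """
    if params.beta <= 0.0:
        raise ValueError("ring model requires beta > 0 (chi is undefined at 0)")
    P = ring_eigenvectors(d)
    A_per = laplacian_matrix(d, "periodic")
    Wb = 0.5 * np.eye(d) - 0.25 * A_per
    gains_b = 0.5 - 0.25 * periodic_laplacian_spectrum(d)
    gains_f = np.array([chi(g, params) for g in gains_b])
    for g1 in gains_f:
        if abs(params.beta * g1 - 1.0) < 1e-12:
            raise ValueError("implicit solve undefined: beta * chi(gamma_p) = 1")
    Wf = P @ np.diag(gains_f) @ P.T

    a, b, l = params.alpha, params.beta, params.lam
    speeds = np.empty(d)
    spreads = np.empty(d)
    for p in range(d):
        g = gains_b[p]
        cg = gains_f[p]
        speeds[p] = ((a - l) * g + b * cg) / (1.0 - b * cg)
        spreads[p] = ring_sigma0(params, g)
        pair = GainPair(float(cg), float(g))
        if abs(rho(0.0, params, pair) - 1.0) > 1e-10:
            raise AssertionError(f"rho_p(0) != 1 for assembly {p}")
        c_num, s_num = _log_expansion(0.0, params, pair)
        if abs(c_num - speeds[p]) > 1e-6 or abs(s_num - spreads[p]) > 1e-6:
            raise AssertionError(
                f"assembly {p}: closed-form (c, sigma) = "
                f"({speeds[p]:.8f}, {spreads[p]:.8f}) disagrees with the "
                f"log-expansion ({c_num:.8f}, {s_num:.8f})")
    return RingModel(d=d, Wb=Wb, Wf=Wf, P=P, gains_b=gains_b, gains_f=gains_f,
                     speeds=speeds, spreads=spreads, params=params)


@dataclass
class RingModeRun:
    p: int
    coeff: float
    field: SpaceTimeField              # scalar BVP run of assembly p
    kind: str                          # "front" | "stationary" | "ratio undefined"
    ratio: Optional[float]             # stationary decay ratio, if defined


@dataclass
class RingSummary:
    modes: list[RingModeRun]
    reconstruction: SpaceTimeField     # E_j^n = sum_p u_{j,p}^n U_p
    ring: RingModel

    def approximation(self, n: int, J: int) -> np.ndarray:
        """Closed-form profile approximation at step n, layers 0..J.

        Propagating assemblies (c_0^p > 0) contribute erf fronts, blocked
        assemblies their bounded stationary geometric profiles.
        """
        js = np.arange(J + 1)
        out = np.zeros((J + 1, self.ring.d))
        for run in self.modes:
            if run.coeff == 0.0:
                continue
            c, s = self.ring.speeds[run.p], self.ring.spreads[run.p]
            if run.kind == "front":
                prof = 0.5 * run.coeff * (1.0 - erf((js - c * n) / np.sqrt(4 * s * n)))
            elif run.kind == "stationary":
                prof = run.coeff * run.ratio ** js
            else:
                continue
            out += np.outer(prof, self.ring.P[:, run.p])
        return out


def ring_mode_summary(ring: RingModel, input_coeffs: np.ndarray,
                      n: int, J: int) -> RingSummary:
    """Run each assembly's boundary-value problem and reconstruct the field.

    ``input_coeffs`` are the coefficients a_p of the input on the assembly
    basis; each assembly follows the scalar semi-infinite recurrence with
    gains (chi(gamma_p), gamma_p) and constant source a_p.
    """
    input_coeffs = np.asarray(input_coeffs, dtype=float)
    if input_coeffs.shape != (ring.d,):
        raise ValueError(f"expected {ring.d} input coefficients")
    if not np.all(np.isfinite(input_coeffs)):
        raise ValueError("input coefficients must be finite")
    a, b, l = ring.params.as_tuple()
    modes: list[RingModeRun] = []
    U = np.zeros((n + 1, J + 1, ring.d))
    for p in range(ring.d):
        ap = float(input_coeffs[p])
        g, cg = float(ring.gains_b[p]), float(ring.gains_f[p])
        init = np.zeros(2)
        init[0] = ap
        field = simulate_lattice(init, ring.params, GainPair(cg, g),
                                 n_steps=n, domain="semi_infinite", source=ap,
                                 certify=False)
        if l * g == 0.0:
            kind, ratio = "ratio undefined", None
        elif ring.speeds[p] > 0:
            kind, ratio = "front", (a * g + b * cg) / (l * g)
        else:
            kind, ratio = "stationary", (a * g + b * cg) / (l * g)
        modes.append(RingModeRun(p=p, coeff=ap, field=field, kind=kind, ratio=ratio))
        U[:, :, p] = field.scalar[:, :J + 1]
    E = U @ ring.P.T
    recon = SpaceTimeField(E, j_offset=0, domain="semi_infinite")
    return RingSummary(modes=modes, reconstruction=recon, ring=ring)
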