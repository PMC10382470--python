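"""Closed-form asymptotic predictors and empirical wave statistics.

After n steps the Dirac-initialized lattice run resembles a Gaussian packet
of mass one drifting at the wave speed c and broadening diffusively
(variance ~ 2 sigma n); the semi-infinite boundary-value problem converges
to a geometric stationary profile, a diffusive erf profile, or a traveling
erf front depending on the competition between the feedforward (alpha+beta)
and feedback (lam) gains.  This module evaluates those printed leading-order
profiles and provides the estimators (peak-drift speed, variance-growth
spread, sup-error decay exponent) used to compare them against the exact
simulators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import erf

from .amplification import identity_speeds
from .fields import SpaceTimeField
from .params import Hyperparams


@dataclass(frozen=True)
class GaussianProfile:
    """Leading-order Gaussian packet of a Dirac run.

    ``parity="n_plus_j"`` carries the (1 + (-1)^{n+j}) factor of the
    beta = 0, alpha + lam = 1 case (vanishes when n + j is odd);
    ``parity="n_only"`` the (-1)^n factor of theta0 = pi secondary waves.
    """

    speed: float
    spread: float
    parity: str = "none"           # none | n_plus_j | n_only
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.parity not in ("none", "n_plus_j", "n_only"):
            raise ValueError(f"unknown parity {self.parity!r}")


def gaussian_approx(j, n: int, profile: GaussianProfile):
    """Evaluate the printed Gaussian leading-order profile; vectorizes in j."""
    if n < 1:
        raise ValueError("n must be >= 1")
    j = np.asarray(j, dtype=float)
    c, s = profile.speed, profile.spread
    base = np.exp(-(j - c * n) ** 2 / (4.0 * s * n)) / math.sqrt(4 * math.pi * s * n)
    if profile.parity == "n_plus_j":
        base = base * (1.0 + (-1.0) ** (n + np.asarray(np.round(j), dtype=int)))
    elif profile.parity == "n_only":
        base = base * (-1.0) ** n
    out = profile.amplitude_scale * base
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FrontProfile:
    kind: str                       # stationary_geometric | diffusive_erf
    #                               # | traveling_erf | combined_eq_beta
    ratio: Optional[float] = None
    speed: Optional[float] = None
    spread: Optional[float] = None


def classify_front(params: Hyperparams) -> FrontProfile:
    """Select the boundary-value-problem regime from (alpha, beta, lam).

    alpha + beta < lam: bounded stationary geometric profile with ratio
    (alpha+beta)/lam; alpha + beta = lam: diffusive erf in j/sqrt(n);
    lam < alpha + beta: erf front traveling at c0.
    """
    a, b, l = params.alpha, params.beta, params.lam
    cf = identity_speeds(params)
    if a + b < l:
        return FrontProfile("stationary_geometric", ratio=(a + b) / l)
    if a + b == l:
        return FrontProfile("diffusive_erf", speed=0.0, spread=cf["sigma0"])
    return FrontProfile("traveling_erf", speed=cf["c0"], spread=cf["sigma0"])


def front_approx(j, n: int, params: Hyperparams, s0: float = 1.0,
                 kind: Optional[str] = None):
    """Leading-order profile of the constant-source boundary-value problem.

    When ``kind`` is given it must match the regime selected by the
    hyper-parameters (an ambiguous request raises).  The combined secondary
    oscillation is included when beta > 0, alpha + lam = 1 and
    beta < alpha - lam.
    """
    prof = classify_front(params)
    if kind is not None and kind != prof.kind:
        raise ValueError(
            f"ambiguous case request: parameters select {prof.kind!r}, "
            f"caller asked for {kind!r}")
    j = np.asarray(j, dtype=float)
    a, b, l = params.alpha, params.beta, params.lam
    if prof.kind == "stationary_geometric":
        out = s0 * prof.ratio ** j
    elif prof.kind == "diffusive_erf":
        out = s0 * (1.0 - erf(j / np.sqrt(4.0 * prof.spread * n)))
    else:
        out = 0.5 * s0 * (1.0 - erf((j - prof.speed * n)
                                    / np.sqrt(4.0 * prof.spread * n)))
        if b > 0 and abs(a + l - 1.0) < 1e-12 and b < a - l:
            cf = identity_speeds(params)
            osc = (s0 / (2.0 * (1.0 + b)) * (-1.0) ** np.asarray(np.round(j), int)
                   / np.sqrt(4.0 * math.pi * cf["sigma_pi"] * n)
                   * np.exp(-(j - cf["c_pi"] * n) ** 2
                            / (4.0 * cf["sigma_pi"] * n)))
            out = out - osc
    return float(out) if np.ndim(out) == 0 else out


def ivp_boundary_layer(j, j0: int, n: int, params: Hyperparams):
    """Boundary-generated correction to the semi-infinite Dirac-at-j0 run.

    Returns the printed leading-order approximation of G_bl^n(j, j0) -- the
    reflected Gaussian mass weighted by the geometric boundary factor; zero
    before the packet reaches the boundary (n < j0) and zero on the side
    where the correction is exponentially small.
    """
    if j0 < 1:
        raise ValueError("j0 must be >= 1")
    j = np.asarray(j, dtype=float)
    if n < j0:
        out = np.zeros_like(j)
        return float(out) if out.ndim == 0 else out
    a, b, l = params.alpha, params.beta, params.lam
    cf = identity_speeds(params)
    c0, s0 = cf["c0"], cf["sigma0"]
    c_pi, s_pi = cf["c_pi"], cf["sigma_pi"]
    at_pi = abs(a + l - 1.0) < 1e-12        # secondary wave exists

    def gauss(x, sig):
        return (np.exp(-np.asarray(x, float) ** 2 / (4.0 * sig * n))
                / math.sqrt(4 * math.pi * sig * n))

    out = np.zeros_like(j)
    below = j <= j0
    if c0 < 0:
        fac = ((a + b) / l) ** j
        term = -gauss(-j0 - c0 * n, s0) * fac
        if at_pi and b == 0:
            # beta = 0, alpha + lam = 1 carries the parity factor
            term = -(1.0 + (-1.0) ** n) * gauss(-j0 - c0 * n, s0) * fac
        out = np.where(below, term, 0.0)
        if at_pi and b > 0 and c_pi < 0:
            refl = -((-1.0) ** n) * gauss(-j0 - c_pi * n, s_pi) * ((a - b) / l) ** j
            out = out + np.where(below, refl, 0.0)
    else:
        fac = (l / (a + b)) ** j0
        term = -gauss(j - c0 * n, s0) * fac
        if at_pi and b == 0:
            term = -(1.0 + (-1.0) ** n) * gauss(j - c0 * n, s0) * (l / a) ** j0
        out = np.where(~below, term, 0.0)
        if at_pi and b > 0:
            if c_pi > 0:
                refl = -((-1.0) ** n) * gauss(j - c_pi * n, s_pi) * (l / (a - b)) ** j0
                out = out + np.where(~below, refl, 0.0)
            else:
                refl = -((-1.0) ** n) * gauss(-j0 - c_pi * n, s_pi) * ((a - b) / l) ** j
                out = out + np.where(below, refl, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# empirical estimators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveStats:
    speed_fit: float
    spread_fit: float
    error_decay_exponent: Optional[float]

    def summary(self) -> dict:
        return {"speed_fit": self.speed_fit, "spread_fit": self.spread_fit,
                "error_decay_exponent": self.error_decay_exponent}


def wave_stats_report(field: SpaceTimeField, profile: "GaussianProfile",
                      csv_path=None) -> "WaveStats":
    """Per-step comparison table (n, sup_error, peak_pos, variance) plus the
    fitted summary; optionally written as CSV."""
    import pandas as pd
    vals = np.abs(field.scalar)
    layers = field.layers.astype(float)
    ns = _fit_window(vals.shape[0] - 1)
    rows = []
    for n in ns:
        row = vals[n]
        w = row / row.sum()
        mean = float(np.dot(w, layers))
        approx = gaussian_approx(layers[3:-3], n, profile)
        rows.append({
            "n": int(n),
            "sup_error": float(np.max(np.abs(field.scalar[n, 3:-3] - approx))),
            "peak_pos": _quadratic_peak(row, layers),
            "variance": float(np.dot(w, (layers - mean) ** 2)),
        })
    if csv_path is not None:
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    return empirical_wave_stats(field, profile)


def _quadratic_peak(y: np.ndarray, idx: np.ndarray) -> float:
    """Sub-grid peak position by a parabola through the argmax and neighbors."""
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(idx[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    step = idx[1] - idx[0]
    return float(idx[i] + shift * step)


def _fit_window(n_max: int, lo: int = 50, hi: int = 400,
                n_pts: int = 12) -> np.ndarray:
    hi = min(hi, n_max)
    lo = min(lo, max(2, n_max // 4))
    ns = np.unique(np.round(np.geomspace(lo, hi, n_pts)).astype(int))
    return ns[ns >= 2]


def empirical_wave_stats(field: SpaceTimeField,
                         profile: Optional[GaussianProfile] = None,
                         edge_margin: int = 3) -> WaveStats:
    """Fit speed, spread and Gaussian-error decay from a Dirac run.

    * ``speed_fit``: slope of the interpolated peak position against n.
    * ``spread_fit``: slope of the spatial variance against n, divided by 2
      (Gaussian variance after n steps is 2 sigma n).
    * ``error_decay_exponent``: log-log slope of the sup-norm error against
      ``profile`` (the matched Gaussian) over a geometric window of steps --
      the lattice remainder decays like 1/n so the exponent is near -1.

    Parity (sign- or support-alternating) fields are analyzed on the even
    sublattice of n + j, where the packet lives.
    """
    vals = np.abs(field.scalar)
    if not np.any(vals > 0):
        raise ValueError("degenerate field: all zeros")
    T = vals.shape[0] - 1
    if T < 20:
        raise ValueError("need at least 20 steps for the fits")
    layers = field.layers.astype(float)
    ns = _fit_window(T)

    # parity detection: alternating exact zeros on the odd sublattice of n+j
    mid = vals[T]
    par = (np.arange(vals.shape[1]) + field.j_offset + T) % 2
    odd_mass = mid[par == 1].sum()
    parity_field = odd_mass < 1e-12 * max(mid.sum(), 1e-300)

    peaks, variances = [], []
    for n in ns:
        row = vals[n]
        if parity_field:
            keep = (np.arange(row.size) + field.j_offset + n) % 2 == 0
            row = np.where(keep, row, 0.0)
        w = row / row.sum()
        mean = float(np.dot(w, layers))
        variances.append(float(np.dot(w, (layers - mean) ** 2)))
        peaks.append(_quadratic_peak(row, layers))
    speed_fit = float(np.polyfit(ns, peaks, 1)[0])
    spread_fit = float(np.polyfit(ns, variances, 1)[0] / 2.0)

    exponent = None
    if profile is None and T >= 20:
        profile = GaussianProfile(speed=speed_fit, spread=max(spread_fit, 1e-6),
                                  parity="n_plus_j" if parity_field else "none")
    if profile is not None:
        errs = []
        sl = slice(edge_margin, vals.shape[1] - edge_margin)
        for n in ns:
            approx = gaussian_approx(layers[sl], n, profile)
            errs.append(float(np.max(np.abs(field.scalar[n, sl] - approx))))
        errs = np.asarray(errs)
        good = errs > 0
        if good.sum() >= 3:
            exponent = float(np.polyfit(np.log(ns[good]), np.log(errs[good]), 1)[0])
    return WaveStats(speed_fit=speed_fit, spread_fit=spread_fit,
                     error_decay_exponent=exponent)
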