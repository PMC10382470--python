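"""Hyper-parameter containers for the predictive-coding lattice model.

The discrete model updates the encoding error ``e_j^n`` at layer ``j`` and
step ``n`` with three gains:

* ``alpha`` -- feedforward error-correction gain (gradient of the
  reconstruction error at the layer below),
* ``beta``  -- instantaneous feedforward drive (implicit in time),
* ``lam``   -- feedback error-correction gain (top-down prediction).

The implicit solve requires ``0 <= beta < 1``.  Marginal stability of the
identity-connectivity lattice additionally requires ``alpha + lam <= 1``;
parameter sets violating that bound are accepted (they are useful to
demonstrate instability) but carry ``marginal_ok=False``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Hyperparams:
    """Update gains (alpha, beta, lam) of the discrete recurrence."""

    alpha: float
    beta: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must satisfy 0 <= beta < 1, got {self.beta}")
        if self.alpha < 0.0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")
        if self.lam < 0.0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")

    @property
    def marginal_ok(self) -> bool:
        """True iff alpha + lam <= 1 (marginal-stability bound)."""
        return self.alpha + self.lam <= 1.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.lam)


@dataclass(frozen=True)
class GainPair:
    """Per-assembly connection gains.

    ``gamma_f`` scales the implicit feedforward coupling (eigenvalue of the
    feedforward weight matrix along the assembly), ``gamma_b`` the feedback
    coupling.  ``gamma_f == gamma_b`` is the symmetric Rao-Ballard case and
    ``(1, 1)`` reduces to the identity-connectivity lattice.
    """

    gamma_f: float = 1.0
    gamma_b: float = 1.0

    @classmethod
    def identity(cls) -> "GainPair":
        return cls(1.0, 1.0)

    @classmethod
    def rao_ballard(cls, gamma: float) -> "GainPair":
        return cls(gamma, gamma)

    @property
    def is_identity(self) -> bool:
        return self.gamma_f == 1.0 and self.gamma_b == 1.0

    @property
    def is_symmetric(self) -> bool:
        return self.gamma_f == self.gamma_b

    def check_pole(self, params: Hyperparams) -> None:
        """The implicit solve is undefined when beta * gamma_f == 1."""
        if abs(params.beta * self.gamma_f - 1.0) < 1e-14:
            raise ValueError(
                "implicit solve undefined: beta * gamma_f == 1 "
                f"(beta={params.beta}, gamma_f={self.gamma_f})"
            )


@dataclass(frozen=True)
class ScaledParams:
    """Continuous-time rates (per millisecond).

    These are the ``Delta t -> 0`` limits of the discrete gains,
    ``alpha_t = alpha / Delta t`` and likewise for ``beta_t``/``lambda_t``.
    Time is measured in milliseconds throughout the package; temporal
    frequencies derived from an angular frequency ``omega`` in rad/ms are
    reported as ``1000 * omega / (2 pi)`` Hz.
    """

    alpha_t: float
    beta_t: float
    lambda_t: float

    def __post_init__(self) -> None:
        if self.alpha_t < 0 or self.beta_t < 0 or self.lambda_t < 0:
            raise ValueError("scaled rates must be nonnegative")

    @property
    def drift(self) -> float:
        """Continuum wave speed c~0 = beta_t + alpha_t - lambda_t (layers/ms)."""
        return self.beta_t + self.alpha_t - self.lambda_t

    @property
    def spread(self) -> float:
        """Continuum diffusive spread sigma~0 = (beta_t+alpha_t+lambda_t)/2."""
        return 0.5 * (self.beta_t + self.alpha_t + self.lambda_t)

    def to_discrete(self, dt: float) -> Hyperparams:
        """Discretize with time step ``dt`` (ms): alpha = alpha_t * dt etc."""
        return Hyperparams(self.alpha_t * dt, self.beta_t * dt, self.lambda_t * dt)
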