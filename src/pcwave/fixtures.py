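"""Deterministic generators for the model's canonical inputs.

Every stochastic fixture is a pure function of (kind, parameters, seed): a
dedicated RNG stream is derived from the seed and a per-kind tag, so adding
new fixture kinds never perturbs existing ones.

The fixtures mirror the inputs used in the analysis: a Dirac impulse at one
layer, a constant source at the input layer, the ring model's
"tuned curve plus fixed random noise" input (pure second Fourier mode
a2 = 1, a1 = a3 = 0, higher coefficients drawn from a normal law with
amplitude epsilon = 0.1), a narrow Gaussian bump on the ring of
orientations centered at pi/2, and seeded symmetric commuting weight
pairs.  A feedforward-pass initialization (one implicit sweep with
alpha = lam = 0) is also provided as an optional way to produce initial
layer states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assemblies import ring_eigenvectors
from .lattice import simulate_lattice
from .params import GainPair, Hyperparams

_KIND_TAGS = {
    "dirac": 1,
    "constant_source": 2,
    "tuned_plus_noise": 3,
    "gaussian_bump": 4,
    "random_symmetric_pair": 5,
}

DEFAULT_NOISE_EPS = 0.1


@dataclass(frozen=True)
class Fixture:
    kind: str
    payload: object            # layer sequence, ring profile, or matrix pair
    seed: int


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _KIND_TAGS[kind]]))


def make_fixture(kind: str, size: int, seed: int = 0, **options) -> Fixture:
    """Build a deterministic fixture of the requested kind.

    Parameters
    ----------
    kind
        One of ``dirac``, ``constant_source``, ``tuned_plus_noise``,
        ``gaussian_bump``, ``random_symmetric_pair``.
    size
        Number of layers (dirac), steps (constant_source) or channels d
        (ring / matrix kinds; even d required for ring kinds).
    """
    if kind not in _KIND_TAGS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if size < 1:
        raise ValueError("bad size")

    if kind == "dirac":
        layer = int(options.get("layer", size // 2))
        if not 0 <= layer < size:
            raise ValueError("bad size: dirac layer outside the sequence")
        payload = np.zeros(size)
        payload[layer] = options.get("amplitude", 1.0)
        return Fixture(kind, payload, seed)

    if kind == "constant_source":
        s0 = float(options.get("s0", 1.0))
        return Fixture(kind, np.full(size, s0), seed)

    if kind == "tuned_plus_noise":
        if size % 2 or size < 4:
            raise ValueError("bad size: ring fixtures need even d >= 4")
        eps = float(options.get("eps", DEFAULT_NOISE_EPS))
        P = ring_eigenvectors(size)
        coeffs = np.zeros(size)
        coeffs[1] = 1.0                       # a2 = 1 on the tuned cosine mode
        noise = _rng(kind, seed).normal(size=size - 3)
        coeffs[3:] = eps * noise              # a_p, p >= 4
        profile = P @ coeffs
        return Fixture(kind, {"profile": profile, "coeffs": coeffs, "P": P}, seed)

    if kind == "gaussian_bump":
        if size % 2 or size < 4:
            raise ValueError("bad size: ring fixtures need even d >= 4")
        width = float(options.get("width", 0.15))
        center = float(options.get("center", np.pi / 2))
        theta = np.arange(1, size + 1) * np.pi / size
        # wrap on the half-circle of orientations
        dist = np.minimum(np.abs(theta - center), np.pi - np.abs(theta - center))
        profile = np.exp(-dist ** 2 / (2.0 * width ** 2))
        return Fixture(kind, profile, seed)

    # random_symmetric_pair: commuting symmetric matrices sharing a basis
    d = size
    rng = _rng(kind, seed)
    Q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    Q *= np.sign(np.diag(Q))[None, :]          # deterministic sign convention
    D1 = rng.uniform(-0.9, 0.9, size=d)
    D2 = rng.uniform(-0.9, 0.9, size=d)
    Wf = Q @ np.diag(D1) @ Q.T
    Wb = Q @ np.diag(D2) @ Q.T
    return Fixture(kind, {"Wf": Wf, "Wb": Wb, "basis": Q,
                          "gains_f": D1, "gains_b": D2}, seed)


def feedforward_pass(source: np.ndarray, beta: float, n_layers: int) -> np.ndarray:
    """Initialize layer states by one pure feedforward sweep.

    Runs a single implicit step of the lattice with alpha = lam = 0 from a
    zero state with the given source pinned at layer 0; this is one optional
    way to produce initial conditions for finite-network experiments.
    """
    params = Hyperparams(0.0, beta, 0.0)
    init = np.zeros(n_layers)
    init[0] = float(np.atleast_1d(source)[0])
    field = simulate_lattice(init, params, GainPair.identity(), n_steps=1,
                             domain="semi_infinite",
                             source=float(np.atleast_1d(source)[0]),
                             certify=False)
    return field.scalar[1, :n_layers]
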