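"""A Dirac impulse turns into a traveling Gaussian packet.

Runs the scalar predictive-coding lattice from a unit impulse and compares
the empirically fitted wave speed and spread with the closed forms
c0 = (beta + alpha - lam)/(1 - beta) and sigma0.  The packet drifts toward
deeper layers because the feedforward gains (alpha + beta) outweigh the
feedback gain lam.
"""

import numpy as np

from pcwave import (GainPair, GaussianProfile, Hyperparams,
                    empirical_wave_stats, identity_speeds, simulate_lattice)

params = Hyperparams(alpha=0.4, beta=0.3, lam=0.3)
field = simulate_lattice(np.array([1.0]), params, GainPair.identity(),
                         n_steps=200)

cf = identity_speeds(params)
stats = empirical_wave_stats(field, GaussianProfile(cf["c0"], cf["sigma0"]))

print(f"closed-form speed  c0     = {cf['c0']:.4f} layers/step")
print(f"fitted peak-drift speed   = {stats.speed_fit:.4f}")
print(f"closed-form spread sigma0 = {cf['sigma0']:.4f}")
print(f"fitted variance-growth/2  = {stats.spread_fit:.4f}")
print(f"sup-error decay exponent  = {stats.error_decay_exponent:.2f} "
      "(the Gaussian approximation error shrinks like 1/n)")
print(f"mass at n=200             = {field.layer_sum()[-1]:.12f} "
      "(conserved by the update rule)")
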