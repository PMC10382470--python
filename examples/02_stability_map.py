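"""Stability classification from the amplification factor.

|rho(theta)| <= 1 for all spatial frequencies keeps network activity
bounded; the identity-connectivity lattice is marginally stable exactly when
alpha + lam <= 1, with an extra oscillatory tangency at theta = pi when
alpha + lam = 1.  Assembly gains gamma rescale the picture: large |gamma|
destabilizes when the feedforward error correction alpha is strong.
"""

from pcwave import GainPair, Hyperparams, classify_stability, region_of, wave_modes

cases = [
    (Hyperparams(0.3, 0.2, 0.3), GainPair.identity()),
    (Hyperparams(0.6, 0.2, 0.4), GainPair.identity()),   # alpha + lam = 1
    (Hyperparams(0.7, 0.0, 0.5), GainPair.identity()),   # alpha + lam > 1
    (Hyperparams(0.2, 0.2, 0.3), GainPair.rao_ballard(2.0)),
]

for params, gains in cases:
    v = classify_stability(params, gains)
    modes = wave_modes(params, gains) if v.status != "unstable" else []
    desc = ", ".join(f"theta0={m.theta0:.2f}: c={m.speed:+.3f}, "
                     f"sigma={m.spread:.3f}" for m in modes) or "-"
    print(f"alpha={params.alpha}, beta={params.beta}, lam={params.lam}, "
          f"gamma={gains.gamma_b}: {v.status} (max|rho|={v.max_modulus:.3f}) "
          f"modes: {desc}")

print()
print("(beta, lam) quadrant region of (0.2, 0.3):", region_of(0.2, 0.3),
      "- the region fixes which gamma boundaries shape the stability map")
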