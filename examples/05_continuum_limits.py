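"""Continuum limits: lattice ODE, transport and heat equations.

Rescaling the gains by the time step turns the recurrence into a lattice
ODE whose packet drifts at c~0 = beta_t + alpha_t - lambda_t; making depth
continuous yields a pure transport equation, or -- at the exact feedforward/
feedback balance -- a heat equation with diffusivity delta * sigma0.
"""

import math

import numpy as np

from pcwave import (GainPair, Hyperparams, PdeSpec, ScaledParams,
                    closed_form_pde, empirical_wave_stats,
                    integrate_lattice_ode, width_diffusion_coefficient)

sc = ScaledParams(alpha_t=0.2, beta_t=0.1, lambda_t=0.05)   # per ms
init = np.array([0.0, 1.0, 0.0])
field = integrate_lattice_ode(init, sc, GainPair.identity(), t_end=120.0,
                              dt_out=1.0, j_initial=-1)
st = empirical_wave_stats(field)
print(f"lattice ODE: predicted speed {sc.drift:.3f} layers/ms, "
      f"fitted {st.speed_fit:.3f}; predicted spread {sc.spread:.3f}, "
      f"fitted {st.spread_fit:.3f}")

spec = PdeSpec("transport", advection=0.5, boundary=1.0,
               initial=lambda x: 0.0)
print(f"transport limit: e(t=10, x=2) = {closed_form_pde(spec, 10.0, 2.0):.3f} "
      "(behind the front, the source value has arrived)")

heat = PdeSpec("heat", diffusion=0.25, boundary=1.0)
x = math.sqrt(4 * 0.25 * 4.0)
print(f"balanced case (heat limit): e(t=4, x={x:.2f}) = "
      f"{closed_form_pde(heat, 4.0, x):.5f} = 1 - erf(1)")

wd = width_diffusion_coefficient(Hyperparams(0.2, 0.1, 0.4), 1.0, 1.0)
print(f"width-diffusion coefficient (xi_f = xi_b = 1): {wd.coefficient:.3f} "
      f"-> {'well-posed' if wd.stable else 'ill-posed'} smoothing across "
      "the layer width")
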