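# Methods

## Model

`pcwave` studies the linear dynamics of a hierarchical predictive-coding
network. The state `E_j^n ∈ R^d` is the activity of layer `j` at discrete
step `n`; each update combines an instantaneous feedforward drive (gain
`β`, implicit in time), a memory term, a feedforward prediction-error
correction (gain `α`, driven by the reconstruction error of the layer
below) and a feedback error correction (gain `λ`, driven by the top-down
prediction). With feedforward/feedback weight matrices `Wf`, `Wb` the
interior update is

    E_j^{n+1} = β Wf E_{j-1}^{n+1} + α Wbᵗ E_{j-1}^n
                + [(1-β-λ) I - α Wbᵗ Wb] E_j^n + λ Wb E_{j+1}^n .

Layer 0 is pinned to a source (the sensory input); the top layer has no
incoming feedback and uses the same update with the `λ` term removed. The
admissible gains are `0 ≤ β < 1` (the implicit solve needs it) and
`α, λ ≥ 0`; the network is marginally stable — active but bounded — exactly
when `α + λ ≤ 1`, and parameter sets violating that bound are accepted but
flagged (`Hyperparams.marginal_ok`), since demonstrating instability is part
of the package's purpose.

All behavior is read from the amplification factor: inserting a spatial
Fourier mode `e^{ijθ}` into the scalar (per-assembly) recurrence gives the
one-step complex gain

    ρ(θ) = [α g₂ (e^{-iθ} - g₂) + 1 - β + λ (g₂ e^{iθ} - 1)]
           / (1 - β g₁ e^{-iθ}) ,

with assembly gains `(g₁, g₂)` — `(1, 1)` for identity connectivity,
`(γ, γ)` for symmetric (Rao–Ballard) weights, `(γ₁, γ₂)` in general.
`max_θ |ρ|` classifies stability; at a tangency `|ρ(θ₀)| = 1` the local
expansion `log ρ(θ₀+θ) ≈ -i c θ - σ θ²` yields a Gaussian wave packet of
speed `c` (positive = feedforward, toward deeper layers) and diffusive
spread `σ` (variance `≈ 2σn` after `n` steps).

## Parameters that matter

| parameter | meaning | units | typical values |
|---|---|---|---|
| `α` | feedforward error-correction gain | per step | 0.1–0.7 |
| `β` | instantaneous feedforward gain | per step | 0–0.5 |
| `λ` | feedback error-correction gain | per step | 0.1–0.6 |
| `γ_f, γ_b` | assembly (eigen-)gains of `Wf`, `Wb` | – | −3–3 |
| `α̃, β̃, λ̃` | continuous-time rates (`α/Δt`, …) | per ms | 1/α̃ ≈ 5–20 ms |
| `τ` | transmission delay between layers | ms | 5–20 |
| `ϱ` | feedback/feedforward ratio `λ̃/α̃` | – | 0–3 |
| `k` | delay in steps (discrete model) | steps | 0–3 |

Time is milliseconds throughout; an angular frequency `ω` in rad/ms is
reported as `1000·ω/(2π)` Hz. These conventions put the physiologically
interesting delays (5–20 ms) onto the 7–60 Hz oscillation bands.

## Simulators (module `lattice`)

The implicit left coupling `β g₁ e_{j-1}^{n+1}` is strictly lower
triangular in `j`, so each step is resolved exactly by one left-to-right
forward substitution sweep, implemented as a first-order linear recursive
filter (O(J) per step, no matrix inversion). For the `d`-channel model the
sweep applies `β Wf` per layer.

Infinite-lattice runs are truncated to a window
`[j_min − N − 8, j_max + ⌈max(1, c₀+6σ₀+1)⌉·N + 8 + m_β]`, where `(c₀, σ₀)`
come from the log-expansion of `ρ` at `θ=0` and `m_β = ⌈log 1e−15 / log(βγ_f)⌉`
accounts for the geometric tail the implicit sweep leaks rightward each
step (without it, short runs with large `β` would spuriously touch the
edge). After every run a certificate asserts that the relative magnitude on
the truncation edges stayed below 1e−13, i.e. the window behaved like the
infinite lattice; violations raise, they are never silently accepted.
Semi-infinite runs keep the model's own physical top boundary (the
no-feedback rule) at the truncation layer, again certificate-guarded.

The delayed recurrence (delay `k` steps on both error-correction terms)
needs `2k+1` initial layer sequences. Two independent routes are
implemented and must agree exactly: the direct iteration of the scalar
equation, and a companion form on the history vector
`E_j^n = (e_j^{n-2k}, …, e_j^n)` with matrices `Q₀` (superdiagonal of ones,
last row `(-α, 0, …, 0, 1-β-λ)`) and `Q_{±1}` (single unit entries at
columns `2k+1` and `k+1` of the last row). History buffers are ordered
oldest→newest; `k = 0` reduces to the plain lattice.

Layers and steps are 0-based; `SpaceTimeField` carries an explicit
`j_offset` so truncated windows keep absolute layer labels.

## Spectral analysis (module `amplification`)

* Stability grid: 4096 uniform `θ` points on `[−π, π]` plus exact checks at
  `θ ∈ {0, ±π}`; "marginally stable" requires `max|ρ| ∈ 1 ± 1e−10` with
  grid-isolated tangencies. For identity gains the verdict is cross-checked
  against the closed criterion (`α+λ ≤ 1`, tangency at `π` iff `α+λ = 1`).
* Speeds and spreads: 5-point central differences of `log ρ` with step
  1e−4 (`c = −Im ∂_θ`, `σ = −½ Re ∂_θ²`). Closed forms, where they exist,
  are cross-checked against this expansion to 1e−6 and a mismatch raises.
* Boundary objects of the symmetric analysis: the quadratic roots
  `γ±⁰` of `ρ_γ(0) = −1`, the ratio bound `(λ+β)/α`, the `Λ` threshold
  (only for `λ+β < 1`), the `χ`/`ζ` curves (`β > 0` only), and the
  five-region partition of the `(β, λ)` quadrant with ties resolved by the
  defining weak/strict inequalities.
* One analytic claim did not survive numerical scrutiny and is therefore
  not asserted: for `α+λ < 1` the positive root `γ₊⁰` is *not* in general
  larger than `1 + (1−β)/α` (e.g. `(α,β,λ) = (0.2,0.2,0.3)` gives
  `γ₊⁰ = 3.589 < 5`); the tests instead verify both roots directly through
  `ρ_γ(0) = −1`.

## Assemblies and the ring model (module `assemblies`)

Symmetric commuting weight pairs are jointly diagonalized: `eigh` on `Wb`,
then a secondary diagonalization of the projected `Wf` inside each
(near-)degenerate eigenspace. Ordering is by ascending feedback gain, signs
fixed by making each column's first nonzero component positive, and the
commutation tolerance is `1e−8 · ‖Wf‖_max ‖Wb‖_max`. Non-commuting pairs
are rejected — the decoupling analysis requires joint diagonalizability.

The ring of orientations uses the explicit cosine/sine eigenbasis of the
periodic Laplacian rather than a numerical eigensolver: the degenerate
cos/sin planes would otherwise be returned in an arbitrary rotation and the
mode indices `p` would not be reproducible. `Wb = I/2 − A_per/4` gives
feedback gains `1/2 + sin²(pπ/d) ∈ [1/2, 3/2]`; `D^f = χ(D^b)` makes every
assembly marginally stable (`ρ_p(0) = 1`) with closed-form speed `c₀^p` and
spread `σ₀^p`, both cross-checked against the numerical expansion to 1e−6
at build time (a mismatch fails the build). Ring boundary-value runs size
their depth through the truncation certificate; the demonstrations use
`J ≈ 8–12` probed layers with `n = 150–200` steps, enough for the
propagating fronts to traverse the probed depth.

## Asymptotic predictors (module `asymptotics`)

Closed-form leading-order profiles: the Gaussian packet (with the
`(1+(−1)^{n+j})` parity factor in the explicit balanced case and `(−1)^n`
for secondary waves), the boundary-value trichotomy (geometric stationary
profile with ratio `(α+β)/λ`, diffusive erf in `j/√n` at the exact balance,
traveling erf front at `c₀`), and the reflected-Gaussian boundary-layer
correction of the initial-value problem (zero before the packet reaches the
boundary at `n = j₀`).

Empirical estimators: peak position by quadratic interpolation through the
argmax and its neighbors (parity fields are analyzed on the even sublattice
of `n+j`), spatial variance slope divided by 2, and the sup-error decay
exponent from a least-squares fit on a geometric grid of steps
`n ∈ [50, 400]` (the transient is excluded because the asymptotic constants
are unknown). Error norms exclude a 3-layer margin at the window edges, and
front comparisons are restricted to `j ≤ 0.8·n·max(1, c₀+1)` since the
leading-order formulas hold only below a linearly growing depth.

Two deliberate limitations of what is asserted: the remainder bounds are
checked as decay *rates* (exponent `−1 ± 0.2`), never as constants; and the
amplitude prefactor of the secondary oscillatory term in the combined
two-wave front formula overestimates what exact runs produce (observed
factor ≈ 0.15 instead of `1/(2(1+β)) ≈ 0.42` at `(0.7, 0.2, 0.3)`, stable
under refinement in `n`), so tests assert the verified structure — sign
pattern, packet speed `c_π`, `1/√n` scaling — rather than the constant.

## Continuum limits (module `continuum`)

The lattice ODE (rates `α̃, β̃, λ̃`) is integrated with DOP853 at
`rtol 1e−10 / atol 1e−12` on a certificate-guarded window. The fully
continuous limits are evaluated in closed form: the transport equation by
characteristics (with the `c₀ < 0` branch ignoring the source — the
boundary trace is determined by the initial data), and the balanced-case
heat equation by the odd-reflection image kernel with adaptive quadrature
(absolute tolerance 1e−10, domain truncated at eight standard deviations).
The width-diffusion coefficient `κ(βξ_f + (λ−α)ξ_b)/(1−β)` reports
well-posedness of smoothing along the layer-width coordinate.

The delayed lattice ODE is integrated by the method of steps: one
`solve_ivp` segment per delay interval with dense output serving as the
(cubic) history interpolant, step size capped at `τ/20` so interpolation
error stays below the integrator tolerance. Traveling-wave persistence
experiments close the layers into a periodic ring — a modeling choice: the
wave ansatz `cos(ωt + jθ)` is `j`-periodic once `θ` is a rational multiple
of `2π`, and a ring avoids boundary reflections that a truncated line would
inject. The persistence test tunes `α̃` so that a solved `θ` is exactly
commensurate with the ring, making the ansatz an exact solution.

## Delay dispersion (module `dispersion`)

Discrete: the characteristic polynomial of degree `2k+1` is solved by the
companion-matrix method with per-root residual checks; the marginal
frequencies solve the two simultaneous trigonometric equations at `θ = 0`
found by a 4096-point scan of the squared residual plus bounded local
polish. The acceptance tolerance on the residual is 1e−4 by default:
gain values quoted to a few digits place tangencies only approximately on
the unit circle (the reference `k = 2` configuration with `β = 0.3292` has
a best residual ≈ 3e−5, with the root numerically indistinguishable from
`3π/5`), while exact configurations resolve to 1e−12.

Continuous (`β̃ = 0`): homogeneous oscillations have the closed form
`ω = α̃√((1+ϱ)(3−ϱ))`, `τ = (2kπ − arccos((ϱ−1)/2))/ω` for `ϱ ∈ [0, 3)`
(smallest positive `τ` at branch `k = 1`; none for `ϱ ≥ 3`). Traveling
waves follow the analytical case split — `ϱ = 0` and `ϱ = 1` in closed
form, otherwise roots of the reduced scalar equation bracketed on
`(0, π/τ)` by a 4000-point scan plus Brent refinement (duplicates merged at
1e−8), with `θ` recovered by the arctan formula, which is unambiguous
modulo `2π`. Every returned pair is validated against the full
two-equation system to 1e−10. Direction labels: `θ ∈ (0, π)` backward,
`θ ∈ (π, 2π)` forward.

Branch continuation in `ϱ` matches solutions at consecutive grid points by
nearest neighbors in `(ωτ, θ)` — the `θ` distance disambiguates the `ω`
crossing at `ϱ = 1` — and refuses grids coarser than 0.05. The secondary
branch's analytic emergence threshold is implemented as
`ϱ_c = (4α̃τ−1)/(4α̃τ+1)`, the form consistent with the existence condition
`4α̃τ > (1+ϱ)/(1−ϱ)` (the sign-flipped variant is negative for the
reference configuration `4α̃τ = 3.2` and cannot be an emergence point in
`(0,1)`); the numerically detected emergence is reported alongside as a
cross-check. The fold `ϱ₀` where both branches vanish is bisected to 1e−6
on the root count, and the secondary branch's `θ = π` crossing (direction
reversal) is bisected on `θ − π`. Existence below `ϱ = 1` is governed by
*two* sufficient mechanisms — the slope condition `4α̃τ > (1+ϱ)/(1−ϱ)` and
the tangency condition `4α̃τ ≥ π − arccos(2ϱ/(1+ϱ²))` — and tests assert
non-existence only below the minimum of the two (treating either alone as
necessary is numerically wrong: at `ϱ = 0.2` a genuine solution exists
below the tangency bound).

## Synthetic inputs (module `fixtures`)

Every fixture is a pure function of `(kind, parameters, seed)`; a dedicated
RNG stream is derived from the seed and a per-kind tag so adding fixture
kinds never perturbs existing ones. The kinds mirror the canonical inputs
of the analysis: a Dirac impulse; a constant source; the ring's
"tuned curve plus noise" (`a₂ = 1`, `a₁ = a₃ = 0`, higher coefficients
normal with amplitude `ε = 0.1`); a narrow Gaussian bump on the orientation
half-circle centered at `π/2` (width 0.15 rad — narrow relative to the
ring's lowest modes, chosen so the bump carries many Fourier modes and the
coarse-to-fine arrival ordering is visible); and seeded commuting symmetric
weight pairs built from a shared random orthogonal basis with gains in
`(−0.9, 0.9)` (inside the stable range and away from the `βγ = 1` pole).
A single feedforward-pass initializer (`α = λ = 0` sweep) is provided as an
optional way to produce initial states for finite networks.

What the fixtures do not emulate: learned or data-driven weights,
nonlinear activations, heterogeneous per-layer connectivity, and
measurement noise in time. Passing tests therefore certify the mathematics
of the linear model on its canonical inputs, not the behavior of trained
networks or of recorded neural data.

## Problem sizes and budgets

The default test-suite runs use `n ≤ 400` steps for lattice runs,
`d ≤ 64` channels, 150–400 point `ϱ` grids, and ≤ 40 oscillation periods
for delay-differential runs; these sizes place every asymptotic statement
comfortably inside its fitted window while keeping the whole suite under a
minute on one core. `scripts/acceptance.py` recomputes the dispersion
reference quantities from scratch in a few seconds.

## Known limitations

* The analysis is linear throughout: no activation nonlinearity, no
  learned weights, no second-order-neighbor coupling.
* Non-commuting weight pairs are out of scope (no joint eigenbasis).
* The traveling-wave solver covers `β̃ = 0` only; with an instantaneous
  feedforward drive the dispersion system acquires an extra term that
  this package does not solve.
* Asymptotic constants (`C`, `κ`, the cone constant of the implicit tail)
  are never estimated — only decay rates are asserted.
* The `marginal_frequencies` tolerance admits near-tangencies by design;
  callers needing strict unit-circle roots can pass `resid_tol=1e-9`.
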