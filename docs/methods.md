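# Methods

## Model and assumptions

The package implements a discrete-time SIVS epidemic map on compartments
(I, S, V) with standard incidence βSI/N, constant population N, and a
vaccination program acting on a fraction q of newcomers and on
susceptibles at rate p, with immunity waning at rate ε. Time is a unitless
integer step index (the native map corresponds to the forward-Euler
discretization of the continuous model at step size Δ = 1). Compartments
are real-valued population counts (the worked setting uses millions of
individuals and steps of one day), not integers: the model is
deterministic mean-field, with no demographic stochasticity.

Three equivalent formulations are exposed: the full three-compartment map
(`step_full`, which conserves I+S+V to machine precision because it uses
the state's own total in the incidence term), the reduced two-dimensional
map with V = N − S − I eliminated (`step_reduced`), and the fraction
system on (i, s) = (I/N, S/N) (`step_fraction`). All analysis (equilibria,
Jacobians, scans) works on the reduced map; the equivalences are
property-tested.

## Parameters

| name | meaning | units | constraint |
|------|---------|-------|------------|
| μ | natural death (= birth) rate | 1/time | > 0 |
| β | contact rate | 1/time | ≥ 0 |
| γ | cure rate | 1/time | ≥ 0 |
| ε | immunity-waning rate | 1/time | ≥ 0 |
| p | vaccination rate of susceptibles | 1/time | ≥ 0 |
| q | vaccinated fraction of newcomers | — | [0, 1] |
| N | population size | individuals | > 0 |

The conditions μ+p+ε+β < 1 and μ+γ < 1 are sufficient (not necessary) for
orbits started with nonnegative compartments to stay nonnegative; they are
reported by `validate_conditions` but never enforced, because the
bifurcation analysis deliberately iterates the raw map with β up to 4.
States leaving the admissible region {I ≥ 0, S ≥ 0, I+S ≤ N} are never
clipped; `simulate` records the first violating step index.

## Equilibria and thresholds

All equilibrium quantities are closed-form: R₀, the disease-free point Q⁰,
the endemic point Q* (reported absent when R₀ ≤ 1 — at R₀ = 1 it merges
with Q⁰ and the I* formula evaluates to 0), the no-vaccination reproduction
number β/(μ+γ), and the normalized forward sensitivity indices
ψ_q = −qμ/[(1−q)μ+ε] and ψ_p = −p/(μ+p+ε). The sensitivity closed forms are
cross-checked in tests against central differences of R₀ with relative step
1e−6, which would catch transcription errors.

Stability is classified through the 2×2 Jacobian and the Jury (Schur–Cohn)
conditions |tr| < 1+det < 2, verified in tests against a brute-force
root-modulus oracle on a (trace, determinant) grid (points within 1e−9 of
the stability boundary are excluded from the comparison — root finding is
ill-conditioned exactly on the boundary). Verdicts are
stable/unstable/marginal with "marginal" reserved for |R₀ − 1| < 1e−9 at
the disease-free point and a spectral radius within 1e−9 of 1 at the
endemic point; marginal cases are excluded from stable/unstable property
counts.

Analytic thresholds: the transcritical contact rate solves R₀(β) = 1; the
period-doubling contact rate puts an eigenvalue at −1, i.e. solves
R₀ = 1 + (2[2−(μ+p+ε)]/(2−(μ+ε)))·((μ+ε)/[(μ+p+ε)(μ+γ)]). Both are
cross-checked against bisection oracles on the corresponding characteristic
polynomial sign changes. The endemic discriminant b₁² − 4b₂ is positive for
every R₀ > 1 parameter set (property-tested), so the endemic eigenvalues
are real and no Neimark–Sacker bifurcation can occur;
`no_neimark_sacker_certificate` evaluates this per parameter set.

## Numerical scans and period detection

`bifurcation_scan` iterates the raw reduced map from a fixed initial state
over an ascending parameter grid, discards `n_transient` steps, and records
`n_sample` values of I_t. The attractor period is the smallest k ≤ 64 with
|x_{t+k} − x_t| < 1e−6·N across all samples; failing that the point is
labelled aperiodic. Non-finite orbits are flagged per grid point and the
scan continues. Detected thresholds: the transcritical onset is the first
grid value whose post-transient mean I exceeds 1e−6·N; the flip onset is
the first grid value with a period-2 attractor; `period1_loss` is the first
value whose attractor is not a fixed point (used for Euler Δ-scans).

Transient length matters near thresholds because of critical slowing-down:
the relaxation rate toward the fixed point scales like (μ+γ)|R₀−1|, so at
a grid distance of 0.001 from the threshold the orbit needs on the order of
10⁴–10⁵ steps to settle. The general-purpose default is `n_transient=2000`
(ample away from criticality); the acceptance-grade threshold scans use
50 000-step transients, which localize the transcritical onset, the flip
onset, and the Euler step-size threshold each to within one 0.001 grid step
of the analytic values. With shorter transients the detectors report the
decaying remnant instead of the attractor (the onset appears several grid
steps early, and the alternating decay below the flip point can masquerade
as a period-2 orbit).

Lyapunov exponents use the standard Benettin scheme: the tangent map along
the post-transient orbit is accumulated with QR re-orthonormalization every
step, and the exponents are the averaged logs of the R diagonal, sorted
descending. For orbits converging to a stable fixed point the leading
exponent matches ln(max|eig J|) at the fixed point to better than 1e−3 with
2000 iterations (tested); chaotic-band estimates use 10⁴ iterations.

For the worked parameter set (μ=0.1, γ=0.15, ε=0.25, p=0.2, q=0.4) the
measured cascade of the reduced map is: transcritical at β ≈ 0.4435, first
flip at β ≈ 2.4279, secondary flip (period 2 → 4) in (3.2, 3.25), with
period-4 at β = 3.3 (leading exponent ≈ −0.27) and a chaotic band with
positive leading exponent (≈ +0.24) by β = 3.45–3.48. Attractors can
coexist off the main branch (a period-6 basin and escaping orbits were
observed at β = 3.3 from other initial states), so scan results are always
tied to the recorded initial state.

## Euler discretization

`euler_step` applies the forward-Euler map of the continuous model with
step size Δ; at Δ = 1 it is algebraically identical to the native reduced
map, and its fixed points are Δ-independent. The Jacobian follows the
analytic entry pattern I + Δ·(continuous Jacobian). For R₀ < 1 the
guaranteed disease-free stability bound is min{2/(μ+p+ε), 2/[(μ+γ)(1−R₀)]}
— the two per-eigenvalue conditions must hold jointly, so the simultaneous
bound is the minimum; the alternative grouping 2/min{·,·} (the larger, not
sufficient, of the two) is exposed separately as
`dfe_delta_bound_printed` for comparison. For R₀ > 1 the critical step
size Δ* = (b₁ − √(b₁²−4b₂))/b₂ is returned with both roots; the Schur–Cohn
condition P(−1) > 0 always fails first (r₁ < b₁/b₂, property-tested), so
crossing Δ* produces a numerically induced flip bifurcation.

## Fixtures and what the tests show

Property tests draw random parameter sets by rejection sampling into
regimes (nonnegativity conditions satisfied; R₀ below/above 1; β relaxed
up to 4) with rates sampled uniformly on ranges matching the worked
setting (μ ∈ [0.01, 0.3], γ ∈ [0, 0.5], ε ∈ [0, 0.4], p ∈ [0, 0.4],
q ∈ [0, 1], N ∈ [0.5, 10]), plus Dirichlet-distributed admissible initial
states. These fixtures exercise the model's own mathematical structure;
they do not emulate real surveillance data (no observation noise, no
integer counts, no parameter uncertainty), so passing tests certify the
dynamical-systems analysis, not epidemiological fit to any dataset.

## Known limitations

- Deterministic, constant-population model: no demographic noise, no
  disease-induced mortality, no time-varying rates.
- Bifurcation detection is grid-based; thresholds are localized to one
  grid step, not continued to machine precision (the analytic formulas
  serve that purpose where they exist).
- Period detection is capped at period 64; longer cycles are reported as
  aperiodic.
- The necessary (as opposed to sufficient) conditions for nonnegativity of
  solutions are not characterized; admissibility outside the sufficient
  conditions is only checked empirically per orbit.
- No continuous-time ODE integration and no center-manifold/normal-form
  coefficients: bifurcations are located, not unfolded.
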