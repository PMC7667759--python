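# sivs — a discrete-time SIS epidemic model with vaccination

`sivs` is a simulator and analysis library for a discrete-time
susceptible–infected–vaccinated–susceptible (SIVS) epidemic model: an SIS
model with standard incidence, vital dynamics, and a perfect-but-temporary
vaccination program. It is aimed at mathematical epidemiologists and
students of discrete dynamical systems who want the full analysis pipeline
for this family of maps — update maps and trajectories, closed-form
equilibria and basic reproduction number, Jury-condition stability
classification, analytic and numerically detected bifurcation thresholds,
Lyapunov exponents, and the forward-Euler discretized variant with its
step-size stability bounds.

## The model

A closed population of constant size N is split into susceptibles S_t,
infecteds I_t and vaccinateds V_t. Per unit time: μ is the natural
death/birth rate, β the contact rate, γ the cure rate, ε the rate of losing
vaccine immunity, p the vaccination rate of susceptibles, and q the
vaccinated fraction of newcomers. The map is

    I_{t+1} = β S_t I_t / N + [1 − (μ+γ)] I_t
    S_{t+1} = (1−q) μ N − β S_t I_t / N + [1 − (μ+p)] S_t + γ I_t + ε V_t
    V_{t+1} = q μ N + p S_t + [1 − (μ+ε)] V_t

Since N is conserved, V can be eliminated (V = N − S − I), leaving a
two-dimensional map whose behaviour is governed by the basic reproduction
number

    R₀ = β [(1−q)μ + ε] / [(μ+p+ε)(μ+γ)].

The disease-free equilibrium Q⁰ = (0, [(1−q)μ+ε]N/(μ+p+ε)) is stable iff
R₀ < 1 (and globally stable for R₀ ≤ 1); the endemic equilibrium
Q* = (I*, (μ+γ)N/β) exists iff R₀ > 1 and is then stable as long as the
nonnegativity conditions μ+p+ε+β < 1, μ+γ < 1 hold. Relaxing β beyond 1
the endemic point loses stability through a period-doubling (flip)
bifurcation, starting a cascade into chaos; a Neimark–Sacker bifurcation is
ruled out (the endemic eigenvalues are always real). The forward-Euler
discretization of the continuous counterpart reproduces the same equilibria
for every step size Δ, but the endemic point is stable only for Δ < Δ*, the
smaller root of b₂x² − 2b₁x + 4 with b₁ = (μ+p+ε) + βI*/N and
b₂ = (μ+ε)βI*/N.

## Worked example

With μ=0.1, β=0.55, γ=0.15, ε=0.25, p=0.2, q=0.4 and initial compartments
(I, S, V) = (0.4, 0.8, 0.5) (so N = 1.7), in units of days and millions of
individuals:

```python
from sivs import ModelParams, basic_reproduction_number, equilibrium_report

params = ModelParams(mu=0.1, beta=0.55, gamma=0.15, epsilon=0.25, p=0.2, q=0.4, N=1.7)
print(equilibrium_report(params))
```

or equivalently from the shell (config file holds the same keys):

```
$ sivs equilibria --config model.yaml
{
  "R0": 1.24,
  "Q0": { "I": 0.0, "S": 0.9581818181818181 },
  "Qstar": { "I": 0.2914285714285714, "S": 0.7727272727272727 },
  "psi_p": -0.36363636363636365,
  "psi_q": -0.12903225806451615
}
```

R₀ = 1.24 > 1: the infection persists, converging to the endemic level
I* ≈ 0.291 million. The sensitivity indices ψ_p, ψ_q are both negative —
raising either vaccination parameter lowers R₀ (at β = 0.4, R₀ = 0.9018 < 1
and the infection dies out instead). The critical Euler step size at
β = 2.7:

```
$ sivs delta-star --config model.yaml --beta 2.7
{
  "b1": 2.548571428571429,
  "b2": 0.6995000000000001,
  "delta_star": 0.8945771837232493,
  ...
}
```

so the Euler-discretized model is stable at the endemic point for
Δ < 0.8946 and flips to a period-2 orbit beyond it. Bifurcation scans
(`sivs scan`, `sivs euler-scan`) write tidy CSVs of post-transient orbit
samples plus JSON sidecars with detected attractor periods, Lyapunov
exponents, and threshold estimates.

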