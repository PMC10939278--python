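# ffsim — fractal-fractional simulator for a tumor–immune model

`ffsim` simulates a five-compartment lung-cancer immunotherapy model — tumor
cells `T`, CD8+ T cells `C`, dendritic cells `D`, the cytokine `IL2`, and an
anti-PD-L1 checkpoint inhibitor `Z` — under a fractal-fractional derivative
with Mittag-Leffler kernel. It is aimed at researchers studying memory
effects (fractional order ξ) and fractal time scaling (dimension λ_f) in
tumor–immune dynamics, who need a tested reference implementation of the
three-point Newton-polynomial scheme for this operator together with the
model's analytic anchors: closed-form equilibria, the next-generation
reproductive number, and Lyapunov stability diagnostics.

## The model

```
dT/dt   = αT(1 − βT) − γT − φCT        tumor: logistic growth, immune kill
dC/dt   = φCT + ρCD − κC               CD8+ cells: stimulation, natural death
dD/dt   = μ − ρCD − ωD − λD            dendritic cells: constant source μ
dIL2/dt = λD − d·IL2                   cytokine sourced from dendritic cells
dZ/dt   = d·IL2 − aZ                   inhibitor produced from IL-2
```

The fractal-fractional operator with Mittag-Leffler kernel (orders
0 < ξ, λ_f ≤ 1, normalization AB(ξ) = 1 − ξ + ξ/Γ(ξ)) replaces d/dt,
giving the Volterra form

```
U(t) = U(0) + λ_f(1−ξ)/AB(ξ) · t^{λ_f−1} F(t, U)
     + ξλ_f/(AB(ξ)Γ(ξ)) ∫₀ᵗ τ^{λ_f−1} F(τ, U) (t−τ)^{ξ−1} dτ ,
```

which `ffsim.simulate` discretizes with quadratic Newton interpolation of the
memory integrand per grid interval (closed-form convolution weights,
`ffsim.newton_weights`). At ξ = λ_f = 1 the scheme collapses to classical
third-order Adams–Bashforth quadrature and is validated against an adaptive
ODE solver.

Analytic anchors:

* disease-free equilibrium `D₁ = (0, 0, μ/(λ+ω), λμ/(d(λ+ω)), λμ/(a(λ+ω)))`;
* interior (endemic) equilibrium from the exact quadratic reduction of the
  steady state, with a residual audit of the published radical closed forms;
* reproductive number `R₀ = μρ/(κ(λ+ω))`;
* Lyapunov function `L = Σ (x − x* − x* log(x/x*))` with its Σ/Ω gain/loss
  split, Mittag-Leffler positivity envelopes, and a uniqueness-condition
  check.

## Worked example

The bundled study parameter set (`ffsim.study_parameters()`: α = 0.0514,
γ = 0.1, κ = 0.02, μ = 480, ω = 0.24, λ = 2·10⁻⁷, d = 3·10⁻⁴, a = 0.04, …) has
no interior equilibrium — tumor decay is driven by γ > α — and a tumor-free
steady state dominated by the dendritic source/decay balance:

```console
$ ffsim equilibria
{
  "disease_free": {
    "C": 0.0,
    "D": 1999.9983333347222,
    "IL2": 1.333332222223148,
    "T": 0.0,
    "Z": 0.00999999166667361
  },
  "disease_free_residual": 1.6526005824218926e-14,
  "endemic": { "feasible": false, ... },
  "reproduction_number": 0.000999999166667361
}
```

`R₀ ≈ 9.99999·10⁻⁴ < 1`, and the dendritic level settles near
μ/(ω+λ) ≈ 2000 while T, C, IL2 and Z decay from the initial state
(T, C, D, IL2, Z)(0) = (1.0, 0.8, 0.3, 0.4, 0.3).

Simulate a sweep of fractional orders at fractal dimension 0.5 and render
the figure panels:

```console
$ ffsim run --lambda-f 0.5 --dt 0.01 --t-end 50 --out out/
wrote 5 trajectories to out/
$ ffsim plot --manifest out/manifest.json --out figs/
wrote 5 figures to figs/
$ ffsim stability --trajectory out/traj_xi1_lf0.5.csv
{ "L": null, ..., "uniqueness_value": ..., "positivity": { "all_positive": true, ... } }
```

Each trajectory CSV has header `t,T,C,D,IL2,Z` at full double precision; the
manifest records the configuration and SHA-256 checksums, and reruns are
byte-identical.

Library use:

```python
import ffsim

params = ffsim.study_parameters()
traj = ffsim.simulate(params, ffsim.FFMOrders(xi=0.8, lambda_f=0.5),
                      ffsim.study_initial_state(),
                      ffsim.SolverConfig(dt=0.01, t_end=50.0))
print(traj.states[-1])   # [0.8731, 0.7559, 911.57, 0.4000, 0.2685]
```

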