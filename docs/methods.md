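# Methods

## Model and assumptions

The simulator integrates a five-compartment tumor–immune system: tumor cells
`T` with logistic self-limitation (`αT(1−βT)`), killed at constant rate `γ`
by dendritic activity and bilinearly (`φCT`) by CD8+ T cells; CD8+ cells `C`
stimulated by tumor contact (`φCT`) and dendritic contact (`ρCD`), dying at
rate `κ`; dendritic cells `D` with constant source `μ`, inactivated by CD8+
contact (`ρCD`) and lost at `ω + λ` (natural death plus conversion into IL-2
signaling); cytokine `IL2` sourced proportionally to `D` and consumed at rate
`d` to produce the anti-PD-L1 inhibitor `Z`, which decays at rate `a`. All
interactions are mass-action; there is no explicit dosing, delay, or noise.
No timescale is attached to the rates: the bundled study parameter set is
treated as unitless.

The model's single symbol clash is resolved by naming: the IL-2 source rate
is `lambda_il2` (model parameter), the operator's fractal dimension is
`lambda_f` (solver parameter). They are never interchangeable.

## Analytic anchors

Setting the vector field to zero on the tumor-free branch (T = C = 0) gives
the disease-free equilibrium `D₁ = (0, 0, μ/(λ+ω), λμ/(d(λ+ω)), λμ/(a(λ+ω)))`,
verified symbolically in the tests. The interior steady state reduces
exactly to a quadratic in `T`,

    αβρφ·T² − P·T + κ(αρ − γρ + φ(ω+λ)) − μρφ = 0,
    P = αβκρ + αρφ − γρφ + φ²(λ+ω),

with discriminant `Q² + 4αβμρ²φ²` where `Q = P − 2αβκρ`, and `C, D, IL2, Z`
recovered by back-substitution. `endemic_equilibrium` evaluates both roots
and returns the first with all components nonnegative (preferring the
smaller tumor burden). The historically published radical closed forms for
this equilibrium are also evaluated (`endemic_equilibrium_printed`): their
`D*/IL2*/Z*` lines coincide exactly with the minus-root reduction, but their
`T*/C*` lines carry sign defects (radicand printed with `−4αβμρ²φ²`, and
three sign flips in the `C*` numerator), so every printed result is gated
behind a residual audit and never trusted as the primary answer. On the
constructed demonstration set (α=2, β=0.5, γ=0.5, φ=1, κ=2, μ=1, ρ=1, ω=0.3,
λ=0.2, d=0.2, a=0.2) the exact reduction returns (1, 0.5, 1, 1, 1) with zero
residual while the printed `T*/C*` radicand is negative.

The next-generation reproductive number is `R₀ = μρ/(κ(λ+ω))`. Note a
modeling caveat we surface but do not resolve: tumor growth in the `T`
equation is controlled by `α` versus `γ`, not by `R₀`, so `R₀ < 1` is
reported as a threshold quantity only, with no claim of tumor extinction.

## The fractal-fractional scheme

With Mittag-Leffler kernel and normalization `AB(ξ) = 1 − ξ + ξ/Γ(ξ)`
(continuous on (0,1], AB(1) = 1), inverting the operator yields the Volterra
form stated in the README. On a uniform grid `t_j = jΔt` the memory integral
is split per interval; on `[t_ν, t_{ν+1}]` (ν ≥ 2) the fractal-weighted rate
`g(τ) = τ^{λf−1}F(τ,U)` is replaced by the quadratic Newton polynomial
through `g_{ν−2}, g_{ν−1}, g_ν` and integrated against `(t_{η+1}−τ)^{ξ−1}`
exactly, producing the three closed-form weights of `newton_weights` (each
validated against adaptive quadrature of its defining integral after the
desingularizing substitution `v = (t_{η+1}−τ)^ξ`).

Design choices where the construction was genuinely open:

* **Initial-condition term.** The literal scheme contains no `U(0)` term (a
  zero vector field would send every state to zero). The default adds `U(0)`
  additively, matching the fractal-fractional integral solution form;
  `ic_term=False` preserves the literal variant for comparison.
* **Startup.** The three-point sums start at ν = 2, leaving the first two
  intervals uncovered. The default `reduced-order` policy integrates
  interval `[t₀,t₁]` with a constant polynomial (`g₀`) and `[t₁,t₂]` with
  the linear polynomial through `g₀, g₁` — in *every* step, so the memory
  integral always spans `[0, t_{η+1}]` and the ξ = λf = 1 limit is a
  complete composite Euler/AB2/AB3 quadrature. The `repeated-first-node`
  policy instead copies node 0 into nodes 1–2 and keeps the truncated sums,
  reproducing the literal scheme.
* **Origin convention.** For λf < 1 the weight `t^{λf−1}` diverges at t = 0;
  the node value `g₀` is assigned the limit convention 0 (the fractal
  measure carries no discrete weight at the origin), logged once per run.
  Consequently node 1 equals node 0 exactly when λf < 1.
* **Kernel exponents.** The kernel is `(t−τ)^{ξ−1}` and the fractal factor
  `τ^{λf−1}`, the standard operator convention; variant renderings of the
  defining integral are treated as typographical. All five compartments use
  the uniform `ξλf/(2AB(ξ)Γ(ξ+3))` prefactor on the third sum.
* **Grids.** Uniform only; non-uniform time grids are rejected at
  construction. Γ is evaluated by the library gamma function.

Cost is O(N) memory (states plus cached rates) and O(η) work per step
(vectorized convolution), O(N²) per run; the default fixture
(dt = 0.01, t_end = 50, N = 5000) integrates in about a second.

### Singular initial layer

For λf < 1 the local term `λf(1−ξ)/AB(ξ)·t^{λf−1}F` is genuinely singular
as t → 0+: early nodes spike, and refining Δt sharpens rather than damps the
spike. Pointwise convergence holds for t > 0 but sup-norm convergence over
the initial layer does not, by construction of the operator. Accordingly the
self-convergence and cross-oracle checks compare trajectories past the
layer (t ≥ 1 and node ≥ 10 respectively); the frozen cross-oracle tolerance
(5% against an independent piecewise-linear first-order quadrature of the
same Volterra form) was established empirically on the scalar decay problem.

### Oracles

* `classical_reference`: adaptive LSODA solution of the classical system
  (rtol 1e-10), the exact limit of the scheme at ξ = λf = 1. The Newton
  scheme matches it to ≤1e-3 relative sup-norm per compartment on the study
  fixture at dt = 0.01, improving under refinement.
* `fractional_quadrature_oracle`: an independent first-order discretization
  of the same Volterra equation (piecewise-linear interpolation of the
  stored rates, exact kernel moments), used only in tests and capped at
  2000 nodes.

## Stability diagnostics

`lyapunov_terms` evaluates `L = Σ(x − x* − x*log(x/x*))` and its published
gain/loss split Σ/Ω (which carries no terms from the `Z` equation; the split
is reproduced as grouped, not re-derived). Strict positivity of state and
equilibrium is required — the function is undefined on the boundary and the
operation refuses rather than regularizes. At an equilibrium both aggregates
reduce to `μ + 2λD*` and `dL = 0`; `Σ < Ω` is reported as a boolean
indicator, not a proof of global stability.

`mittag_leffler` evaluates `E_ξ(z)` by: the exponential identity at ξ = 1;
the truncated power series (terms in log space) wherever the measured
alternating-sum cancellation stays below 1e4; and, for z < 0 with ξ < 1, the
completely monotone spectral integral

    E_ξ(−x) = sin(πξ)/(πξ) ∫₀^∞ exp(−u^{1/ξ} x^{1/ξ}) / (u² + 2u cos πξ + 1) du,

which covers arbitrarily large negative arguments. Verified against
high-precision series summation, `E_½(−x) = e^{x²}erfc(x)`, and the cosine
identity at ξ = 2. Large positive arguments with ξ < 1 (results that
overflow) raise rather than approximate.

`positivity_envelope` returns the Mittag-Leffler lower bound
`X(0)·E_ξ(−b^{1−λf} ξ r t^ξ / (AB(ξ) − (1−ξ)r))` with the per-compartment
decay aggregate `r` assembled from trajectory sup-norms. The "time element"
`b` is a caller-supplied scale defaulting to 1 (the source derivation leaves
it free). A nonpositive denominator makes the bound undefined: the function
warns and returns NaN. For `C` the aggregate `κ − φ‖T‖ − ρ‖D‖` may be
negative, in which case the "lower bound" exceeds the initial value — still
a valid bound statement. `positivity_monitor` is the runtime complement: it
reports per-compartment minima and the first crossing below −1e-9 (the
threshold separating floating-point dust from scheme-induced negativity);
crossings warn, never abort.

`uniqueness_condition` evaluates five growth-bound ratios (each the
bracketed bound divided by the leading coefficient factored out of the
corresponding linear-growth constant — the ratio reading documented here
because the source display is ambiguous) and reports their maximum and
whether it is below 1. A companion boundedness display whose symbols do not
all exist in this model is excluded from implementation.

## Study fixture and sweep

The bundled parameter file `params_paper.yaml` carries the study values
(α = 0.0514, β = 1.02e-9, γ = 0.1, φ = 1e-7, κ = 0.02, μ = 480, ρ = 1e-8,
ω = 0.24, λ = 2e-7, d = 3e-4, a = 0.04) and initial state (1.0, 0.8, 0.3,
0.4, 0.3). The fractional orders behind the reference figure suite are not
recorded at the source; the default sweep ξ ∈ {0.6, 0.7, 0.8, 0.9, 1.0} at
fractal dimensions {0.2, 0.5}, with dt = 0.01 and t_end = 50, is a labelled
stand-in, and figure comparisons are qualitative only (signs of initial
rates, monotone rise of `D` toward μ/(ω+λ) ≈ 2000, decay of the other four
compartments).

## Known limitations

* The scheme is explicit with fixed step; stiff parameter regimes can
  require small Δt, and blow-up is reported (`IntegrationError` naming the
  step), not damped.
* No Caputo or Caputo–Fabrizio kernel variants, no adaptive stepping, no
  corrector iteration, no parameter fitting, and no pharmacokinetic dosing
  model; the stochastic behavior of real tumor–immune systems is out of
  scope.
* Lyapunov diagnostics require a feasible strictly positive interior
  equilibrium; at the study parameters none exists, so the CLI stability
  report returns null Lyapunov fields there.
* The positivity envelopes are diagnostics built from sup-norms of an
  already-computed trajectory; they are not a priori bounds.
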