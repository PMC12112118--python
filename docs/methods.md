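# Methods

## Model

The package treats •OH-driven electrooxidation as a deterministic, lumped,
sequential reaction chain driven by a prescribed radical profile. Three
assumptions shape everything:

1. **•OH is the only oxidant, and its level is slaved to H₂O₂.** The fast
   recombination equilibrium 2 •OH ⇌ H₂O₂ makes the normalised radical level
   proportional to the normalised peroxide level, [•OH]* = k·[H₂O₂]*. All
   transport, scavenging and surface effects are folded into the single
   factor k; nothing mechanistic is claimed about the individual equilibrium
   constants, which are not separately identifiable from this data.
2. **Intermediates are lumped into sequential pools.** Every two-ring
   species is one pseudo-component, every one-ring species another, ending
   in CO₂. Each step is an elementary second-order reaction with •OH;
   reverse reactions are omitted by construction (no configuration hook is
   provided), which is the regime where irreversible electron transfer
   holds, i.e. current densities of roughly 10 mA/cm² and above.
3. **k scales linearly with current density.** One calibration of k(j)
   transfers a single-current experiment across the operating range; the
   H₂O₂ *shape* f(t) is reused unchanged, only its amplitude through k
   varies with j.

Because each pool equation is linear in the pools once [•OH](t) is fixed,
the substitution u(t) = ∫₀ᵗ[•OH]ds turns the system into a constant-
coefficient decay cascade. Its closed-form (Bateman) solution, evaluated at
u(t), must equal the numerically integrated trajectory — this
exposure-transform identity is the package's master correctness oracle and
is enforced in tests to 1e-6 per pool on randomised scenarios.

## Normalisation

Concentrations are normalised by the parent's initial molar concentration
C₀; the same reference is used for H₂O₂, which keeps [•OH]* = k·[H₂O₂]*
dimensionally coherent with the 1/C₀ folded into k. Dimensionless time uses
a fixed scaling factor (default 1·10⁻⁶ s), and dimensionless rate constants
map to absolute ones as k = k*/(scaling·C₀). Simulation itself runs in
absolute time with absolute constants — mathematically identical, but it
keeps the scaling convention confined to the estimator, the only place that
needs it. Note that with the default scaling the BPA-chain optimum sits at
k_S* ≈ 1.31, so the optimiser bounds on dimensionless constants are [~0, 10]
rather than the unit interval; a unit bound would exclude the physical
solution under this convention.

## Parameters and defaults

| parameter | units | default | meaning |
|---|---|---|---|
| B₀..B₃ | –, 1/s, 1/s², 1/s³ | (3.09e-2, 3.39e-4, −3.10e-8, 8.81e-13) | cubic H₂O₂ fit, BPA system, valid on [0, 18000] s |
| k | – | 1e-10 (15 mA/cm²) | •OH/H₂O₂ proportionality |
| k(j) | cm²/mA, – | slope 6.48e-12, intercept 8.55e-12 | current-density law (R² = 0.989) |
| k_S, k_B, k_M | 1/(M·s) | 1.002e10, 3.92e10, 1.387e10 | BPA chain constants |
| C₀ | mol/L | 1.31e-4 (BPA), 1.04e-4 (RhB) | parent initial concentration |
| rtol, atol | – | 1e-8, 1e-10 | RK45 tolerances |
| noise σ | – | 0.04 | synthetic measurement noise (multiplicative), matching the ~4% RMSE scale of the calibration data |

The rhodamine B transfer scenario uses k_S = 9e9 and k_B = k_M = 1.2e10
1/(M·s) with k resolved from the j-law at 20 mA/cm² (1.3815e-10). The j-law
was calibrated on the BPA normalised frame and is applied unchanged in the
rhodamine frame despite the different C₀; this mirrors how the calibration
is used in practice and is a known physical inconsistency of the approach,
not resolved here.

## Numerical choices

- **Integration**: explicit RK45 with dense output; the chain is non-stiff
  at these rate-constant/exposure scales. Mass balance is checked after the
  fact (tolerance 1e-6 per row) instead of being projected in, so solver
  error is surfaced, not hidden. Entries are allowed to undershoot zero by
  1e-9 before clipping for reporting.
- **Bateman evaluation**: the closed form is built symbolically as
  polynomial-exponential terms; rate constants closer than a relative 1e-9
  are merged and handled by the confluent limit (powers of u), never by
  dividing by the rate gap. The rhodamine chain (k_B = k_M exactly) exercises
  this branch. At the 1e-9 boundary the merge itself carries an error of
  order 1e-9·(λu), which is far below every tolerance used downstream.
- **Exposure**: u(t) is an exact piecewise polynomial integral; the cubic is
  clamped at zero between its real roots rather than allowed to go negative.
  Evaluation outside the fitted time window raises instead of extrapolating.
- **Polynomial fitting**: OLS on times rescaled to [0, 1] — a raw-time
  Vandermonde matrix over an 18 000 s window is too ill-conditioned to
  recover cubic coefficients accurately in double precision.
- **Rate-constant estimation**: trust-region-reflective least squares over
  the dimensionless constants, residuals stacked over all pools with equal
  weight (nothing in the data motivates weights), analytic rescaling to
  absolute units afterwards. 95% CIs use the linearised covariance
  s²(JᵀJ)⁻¹ with a Student-t quantile at n−p degrees of freedom; a singular
  Jacobian yields estimates without CIs rather than a failure. Out-of-box
  initial guesses are clipped to the bounds.
- **k calibration**: single-parameter fit in log₁₀(k) (plausible values span
  orders of magnitude), preceded by a coarse deterministic log-grid search
  because the 1-D cost surface is flat both where the parent is untouched
  (k too small) and where it is instantly consumed (k too large).
- **Toxicity**: toxic-unit sum normalised to the parent's potency, so a
  pure-parent state reads exactly 100% regardless of lumping method. Lumped
  pool potency defaults to the arithmetic mean of member potencies (min/max
  selectable); the exact lumping rule for the published pools is not
  documented, and the mean is recorded here as this package's choice.
  CO₂/H₂O carries zero potency. One input quirk is consumed as printed:
  the 4-isopropenylphenol row pairs the name with formula C₉H₁₆O and molar
  mass 140.22 g/mol, which do not match each other; the tabulated mass is
  used as-is. Peak detection is a discrete argmax with earlier-time
  tie-break.

## Synthetic data

The generator emulates hourly aliquot sampling of a batch cell: exact model
values for the pools and the H₂O₂ polynomial on the sampling grid, with
optional seeded Gaussian noise (multiplicative by default, additive
available) clipped at zero. It reproduces the *statistical structure the
estimator assumes* — a shared time base, independent noise, the model being
exactly correct. It does not emulate GC/MS peak-area quantification,
derivatisation chemistry, lumping bias (grouping species with genuinely
different rate constants), or electrode ageing. Passing recovery and
coverage tests therefore demonstrates that the estimation machinery is
self-consistent and calibrated, not that the lumped model is an unbiased
description of any particular real measurement series.

"Degradation of an intermediate" across current densities is deliberately
exposed two ways: net decline from peak, and the fraction of cumulatively
formed material that was further oxidised (`formed_intermediate_turnover`).
Only the turnover reading is consistent with >90% two-ring degradation at
10 mA/cm², so it is the metric used in the headline checks; no single
operationalisation also reproduces the "<1% at ≤5 mA/cm²" phrasing, and
none is forced to.

## Problem sizes

The shipped checks run at desk scale: hourly grids (6 points, 0–5 h) for
estimation — the sampling scheme the scenarios define — and 21–121-point
output grids for trajectories and toxicity profiles; the CI-coverage
experiment uses 25 noisy replicates, which is enough to detect a broken
interval construction while the binomial width (±2.5σ ≈ 11% at n=75
parameter trials) is accounted for in the assertion.

## Known limitations

- Branching pathways, adsorption, scavengers and radical–radical chemistry
  beyond the H₂O₂ equilibrium are out of scope by design.
- At low current density (≤5 mA/cm²) the no-reverse-reaction assumption is
  known to degrade predictive power; the model is most trustworthy at
  ≥10 mA/cm².
- LC₅₀ inputs come from a QSAR consensus tool and inherit its uncertainty;
  toxicity output is a relative index, not a measured endpoint.
- The estimator assumes series on a shared time base and refuses to
  interpolate; resample upstream if needed.
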