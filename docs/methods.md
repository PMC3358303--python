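# Methods

## Generating model and scenarios

Outcomes are simulated from `logit P(D=1|T,C) = β₀ + β₁T + β₂C` with `T`
and `C` coded 0/1 (no centering or effect coding: `β₁` is the
subject-specific treatment log odds ratio conditional on prognosis).
Scenarios are parameterized clinically and converted once:

* `β₀ = logit(p₀)` from the control-arm risk `p₀` among PF-negative
  patients (defaults 0.10 or 0.05);
* a relative risk `r` at baseline risk `p` maps to the log odds ratio
  `log{[rp/(1−rp)] / [p/(1−p)]}` — applied to the treatment RR (0.75 or 1)
  for `β₁` and the PF RR (5 or 2) for `β₂`.

Coefficients are kept at full double precision; 3-decimal values appear
only as test expectations. The conversion refuses `r·p ≥ 1`.

The eight default scenarios cross the two risks, two treatment effects and
two PF strengths. Default grids: per-arm sizes {25, 50, 125, 500, 1000,
2000} — anchored by the two-proportion calculation below, which puts a
moderate-effect trial at ~2000/arm, plus ½, ¼, 1/16 of that and two
small-trial sizes — and PF prevalence λ at 14 values in [0.005, 0.995]
(unconditional) or 11 values in [0.05, 0.95] (conditional, where a 5-point
imbalance is infeasible or vanishingly rare at extreme prevalence).
10,000 replicates per cell by default.

## Trial generation

Unconditional: PF-positive counts per arm are `Binomial(n, λ)`,
independent across arms and of treatment; event counts per (T, C) cell are
Binomial with the cell probability from the generating model. Sampling
cells as binomials equals patient-level Bernoulli simulation in
distribution (cell members are i.i.d.); the test suite verifies this
against an independent per-patient simulator by a chi-square test on the
joint outcome of a 5-patient arm at α = 0.001.

Conditional: PF counts are fixed constants — the design deliberately
conditions on imbalance — `m_control = round(n(λ+0.025))`,
`m_treat = round(n(λ−0.025))`, rounding half away from zero. When rounding
breaks the between-arm gap, `m_treat` is adjusted so that
`m_control − m_treat = round(0.05·n)` exactly: the imposed imbalance is
the design constraint; overall prevalence is matched only up to rounding.
The rounding convention at non-integer `0.025·n` (n = 25, 50, 125) is this
package's choice; results at those sizes can shift slightly under a
different convention. Infeasible cells (counts outside [0, n]) raise, and
the grid runner skips them with a logged manifest entry.

## Imbalance measures

Both measures use continuity-corrected prevalences `(m+0.5)/(n+1)` (0.5
added to each cell), so they are defined even for empty cells. `D₁` is the
absolute difference; `D₂` divides it by the pooled binary SD
`√[(p₁(1−p₁)+p₀(1−p₀))/2]` — the standard two-group standardized
difference for a binary covariate, chosen because it is the form with the
prevalence-invariance the standardized measure is meant to deliver.
Exceedance is closed (`≥`). Ties at a threshold are counted using a 1e-12
tolerance. Curves come either from Monte Carlo (PF counts only; outcomes
are not simulated) or exactly, summing the product binomial pmf over all
`(n+1)²` count pairs; the exact path is bounded at n = 5000 per arm
(O(n²) memory) and is the default in the grid runner.

## Estimation

Both models are fit by maximum likelihood on the four aggregated binomial
cells, which is identical to the patient-level fit (verified against
statsmodels on the expansion). The unadjusted model uses the closed-form
2×2 log OR and SE `√(1/a + 1/(n₁−a) + 1/b + 1/(n₀−b))`; the adjusted
model uses vectorized Newton–Raphson across replicates (relative
log-likelihood tolerance 1e-10, max 100 iterations, step-halving if a step
decreases the likelihood, a 1e-12 ridge on the Hessian for numerical
safety). Wald SEs come from the inverse observed information;
95% CIs use `z = 1.959964`. CIs for both models are evaluated against the
conditional `β₁`: that is the estimand of interest, and it is what makes
the unadjusted model's under-coverage visible.

Degenerate and separated data:

* a PF column constant across all patients (no PF-positive, or none
  PF-negative) drops the PF term; the fit reduces to the unadjusted closed
  form, as it must;
* a diverging MLE (non-convergence, any |coefficient| > 15, or a
  non-finite SE) triggers the fallback: 0.5 added to events and non-events
  of every cell of the model's design, refit, `corrected = True`. The
  unadjusted model corrects when any collapsed 2×2 cell is zero. Replicates
  that still fail are flagged `converged = False`, excluded from the
  primary summaries and counted; the runner always emits an
  `all`-replicates summary variant alongside the `converged_only` one,
  since how such replicates were handled in comparable studies is usually
  unstated.

## Performance metrics

Per (scenario, setting, λ, n, model): bias `mean(β̂₁) − β₁`, empirical SD
(ddof = 1), MSE `mean((β̂₁ − β₁)²)` (so `MSE = bias² + SD²(m−1)/m`
exactly), coverage (CIs containing `β₁`), power (CIs excluding 0). Power
loss is reported two ways: absolute percentage points
`(power_adj − power_unadj)·100`, and relative to the adjusted model,
`(power_adj − power_unadj)/power_adj·100` — the "loss of the unadjusted
model relative to the adjusted model". The reproduction tests use the
relative form, which is the scale the reference series of losses lives on.

ORR deviations: `D_ORR = (1 − exp(β̂₁)) − (1 − OR_true)`, positive =
treatment made to look better than truth. Tables give
`Pr(D_ORR ≥ d)`, `Pr(D_ORR ≤ −d)` and their sum for
d ∈ {0, 0.05, 0.1, 0.15, 0.2, 0.25}; at d = 0 the overall probability is
1 by convention and the over/under split is `Pr(D_ORR ≥ 0)`/`Pr(D_ORR < 0)`.

Sample size: smallest integer n with
`n ≥ (z_{1−α/2}+z_{1−β})²[p₀(1−p₀)+p₁(1−p₁)]/(p₁−p₀)²`, `p₁ = rr·p₀`
(unpooled variance, no continuity correction; a pooled-variance variant is
available). At (0.10, 0.75, 0.05, 0.80) this gives 2002/arm.

## Reproducibility

Every grid cell draws from its own `numpy` stream seeded by
`SeedSequence((base_seed, scenario, setting_code, round(λ·1e6), n))` — an
injective, version-stable mapping (exhaustively tested over the default
grids), so any cell of any table can be regenerated in isolation and a
full rerun is bit-for-bit identical. The manifest records the package
version, the seed derivation, per-cell replicate counts and skipped cells.

## What the generator does and does not emulate

It emulates simple randomization of parallel-group trials with one binary
PF, equal allocation, and binomially generated outcomes; chance imbalance
enters only through the PF sampling. It does not model stratified/blocked
randomization or minimization, unequal allocation, multiple or continuous
prognostic factors, correlated factors, measurement error in the PF, or
dropout — so passing tests show the arithmetic of non-collapsibility and
chance confounding under the stated model, not robustness of adjustment in
messier real trials.

## Problem sizes and numerical choices

The test suite and the reproduction script run full-sized cells — 10,000
replicates, up to 2000 patients per arm — which the vectorized fitter
completes in milliseconds per cell; exact enumeration is used for
imbalance curves wherever n ≤ 5000. Monte-Carlo assertions use
3-standard-error bands at the replicate count of the quantity being
checked. Known limitations: at 25/arm with a rare outcome the corrected
(0.5-augmented) fits dominate and small-sample summaries depend visibly on
that convention; the conditional-design rounding convention likewise
matters at the three smallest sizes; relative power loss is unstable when
both powers are near floor or ceiling.
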