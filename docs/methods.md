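# Methods

## Model

A ramping assay heats an organism at a constant rate *v* (°C/min) from its
acclimation temperature *T*<sub>a</sub> to collapse at the critical
temperature *T*<sub>c</sub>, spanning the heating tolerance
*H* = *T*<sub>c</sub> − *T*<sub>a</sub> over the duration Δ*t* = *H*/*v*.
Biological rates scale with temperature as e<sup>−E/kT</sup>; writing
temperature on the dimensionless scale τ = *T*°/*T*<sub>K</sub>
(*T*° in Celsius, *T*<sub>K</sub> = 273.15) turns that Arrhenius form into
the analytically integrable e<sup>βτ</sup> with
β = *E*/(*k·T*<sub>K</sub>). The rescaled heating tolerance

Δ*t*<sub>r</sub> = ∫<sub>t<sub>a</sub></sub><sup>t<sub>c</sub></sup> e<sup>βτ(t)</sup> d*t*
= (e<sup>βτ<sub>c</sub></sup> − e<sup>βτ<sub>a</sub></sup>) / (βλ)   (constant rate, λ = *v*/*T*<sub>K</sub>)

is the rate-weighted duration of the ramp. Its working hypothesis — a
species expends the same Δ*t*<sub>r</sub> whatever temperature it starts
from, at a given heating rate — yields three derived tools:

1. **Cross-acclimation prediction.** Conserving the budget between two
   starts at the same rate (the rate cancels) gives
   *H*₂ = (*T*<sub>K</sub>/β)·ln(1 + e<sup>β(τ<sub>a1</sub>−τ<sub>a2</sub>)</sup>(e<sup>βH₁/T<sub>K</sub></sup> − 1)).
   This closed form was checked against a root-finding solution of the
   conservation equation before being adopted; the two agree to machine
   precision, and the conservation property itself is the authoritative
   definition wherever an algebraic form is ambiguous.
2. **Inversion.** *T*<sub>c</sub> = (*T*<sub>K</sub>/β)·ln(e<sup>βτ<sub>a</sub></sup> + βλΔ*t*<sub>r</sub>)
   recovers the critical temperature implied by a budget.
3. **Rate transfer.** Empirically the budget falls with heating rate as a
   power law Δ*t*<sub>r</sub>(λ) ∝ λ<sup>−γ</sup>; a budget measured at
   one rate transfers to another by (λ₂/λ₁)<sup>−γ</sup>. Combining 3 and
   2 anchored on one measured assay yields the predicted
   *T*<sub>c</sub>(*T*<sub>a</sub>, *v*) surface.

Under the fixed budget the local acclimation response ratio is
d*T*<sub>c</sub>/d*T*<sub>a</sub> = e<sup>β(τ<sub>a</sub>−τ<sub>c</sub>)</sup>,
strictly between 0 and 1 whenever *T*<sub>c</sub> > *T*<sub>a</sub>: heat
limits rise with acclimation, but always less than one-for-one.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| *E* | 0.66 | eV | activation energy of the rate–temperature scaling; chosen a priori, swept by the sensitivity analysis |
| *k* | 8.617333262 × 10⁻⁵ | eV/K | Boltzmann's constant |
| *T*<sub>K</sub> | 273.15 | K | normalisation temperature (≈ 0 °C); β ≈ 28.04 follows |
| γ | 0.76 | – | rate exponent used for surfaces when no fit is supplied |

Interfaces use °C, minutes and °C/min throughout; β is always derived,
never hard-coded. Expressions of the form ln(e^a + b) are evaluated with
log-sum-exp guards so user-supplied extreme *E* or temperature ranges
cannot overflow.

## Numerical choices

- **Trajectory integration** interpolates sampled temperature profiles
  piecewise-linearly and integrates each piece with the constant-rate
  closed form (expm1-based, accurate as β → 0 and valid for cooling
  segments); the only approximation is the interpolation, so no quadrature
  tolerance exists to tune.
- **β = 0** is handled as the exact limit everywhere (budget = duration,
  prediction = identity, inversion = linear), not by small-ε evaluation.
- **Degenerate assays** (*T*<sub>c</sub> = *T*<sub>a</sub>) get budget 0
  and are flagged (`HeatingAssay.is_degenerate`), not dropped.
- **Duplicate (species, rate) records** are averaged on the log₁₀
  Δ*t*<sub>r</sub> scale before pairing or fitting, since the budget is
  strictly positive and analysed on log axes.

## Statistical fits

All regressions go through statsmodels. Concordance across acclimation
temperatures is OLS of log₁₀ Δ*t*<sub>r</sub> (high) on log₁₀
Δ*t*<sub>r</sub> (low), with the mean absolute log₁₀ deviation from the
identity line reported alongside slope/R², because identity-line deviation
— not R² — is what distinguishes a conserved budget from a merely
correlated one. Prediction skill is OLS of observed on estimated *H*
(natural scale by default, log₁₀ switchable, the orientation fixed as
observed-on-estimated). The power-law exponent is estimated three ways:

- pooled OLS of log₁₀ Δ*t*<sub>r</sub> on log₁₀ λ, with and without
  species-specific intercepts (both are reported since either pooling is
  defensible);
- independent per-species OLS, requiring ≥ 3 distinct rates (a 2-point
  slope has no residual degrees of freedom); species below the threshold
  go to an exclusion report;
- a random-intercept, random-slope mixed model fitted by REML (lbfgs).
  Singular or non-converged fits — including the zero-residual noiseless
  case — fall back to the mean of per-species slopes with an explicit
  warning tag; on balanced designs the two estimators coincide.

The activation-energy sensitivity sweep re-runs concordance and prediction
over an *E* grid; the *E* = 0 row is exactly the unscaled analysis. On
synthetic data the R² profile is nearly flat in *E* — including at
*E* = 0, because species-level variation keeps log-tolerances collinear —
so the sweep's discriminating output is the identity-line deviation, which
is minimal near the generating *E* and jumps when rescaling is dropped.

## Synthetic data

The generator draws, per species: log₁₀ Δ*t*<sub>r</sub>* ~ N(3.0, 0.5)
at a 0.1 °C/min reference rate, γ<sub>s</sub> ~ N(0.76, 0.25) truncated to
[0, 1.2], low *T*<sub>a</sub> ~ U(5, 25) °C with the high treatment 10 °C
above (paired treatments in published compilations average about 10 °C
apart), and one shared heating rate per species from
{0.05, 0.1, 0.5, 1.0} °C/min. Budgets are perturbed by independent
multiplicative lognormal noise (scale σ on the natural-log scale) and
inverted exactly to *T*<sub>c</sub>, so generated tables always satisfy
*T*<sub>c</sub> > *T*<sub>a</sub> and, at σ = 0, every estimator must
recover its generating value exactly. Generation is bit-reproducible given
(seed, config); the priors are recorded in the output metadata.

What the generator does **not** emulate: taxonomy and phylogenetic
covariance, between-study protocol heterogeneity, within-species replicate
structure, or any real covariance between budget, exponent and
acclimation temperature. Passing recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions, not that
real assay data satisfy those assumptions.

## Problem sizes

The default validation runs use 37 species × 4 rates (matching the scale
of typical multi-rate compilations), 200 species for noise-degradation
checks, and 500 replicates for the exponent-recovery study, which yields a
Monte-Carlo standard error on the bias of about 6 × 10⁻⁴ — an order of
magnitude below the RMSE (≈ 0.08 at σ = 0.2).

## Limitations

- The deposited compilations this methodology was developed against are
  not bundled; the default `ColumnMap` for them is provisional until
  checked against an actual deposit.
- No inferential machinery (confidence intervals, p-values) beyond slope,
  intercept, R² and simulation-based recovery summaries.
- No survival-probability / thermal-death-time curve fitting, body-size or
  phylogenetic corrections; the budget framework is deliberately
  parameter-light.
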