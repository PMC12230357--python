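# mrpath

Two-sample Mendelian randomization (MR) with multivariable MR and
product-of-coefficients mediation, for GWAS summary statistics.

`mrpath` is aimed at analysts asking *mediation* questions of the form
"does an exposure (say, body fat percentage) act on a disease outcome
(say, anxiety disorder) through a circulating metabolite?" when only
per-SNP summary effects from non-overlapping GWAS cohorts are available.
It covers the full workflow: instrument selection and LD clumping, allele
harmonization, the five standard univariable causal-effect estimators,
heterogeneity / pleiotropy / directionality diagnostics, multivariable MR
for direct effects, and the two-step mediation decomposition — plus a
summary-level simulator with known causal structure for validating every
step.

## The model

Each genetic instrument *j* contributes a Wald ratio
β̂ⱼ = β̂ⱼ(out) / β̂ⱼ(exp). The inverse-variance-weighted (IVW) estimate
pools them as a zero-intercept weighted regression of outcome betas on
exposure betas, with weights wⱼ = 1/se²ⱼ(out):

    β̂_IVW = Σ wⱼ β̂ⱼ(exp) β̂ⱼ(out) / Σ wⱼ β̂ⱼ(exp)²

Under heterogeneity (Cochran Q, I² = max(0, (Q − df)/Q)·100) the SE is
inflated by √max(1, Q/df) (multiplicative random effects); MR-Egger frees
the intercept, whose deviation from zero measures directional horizontal
pleiotropy; the weighted median and mode estimators provide robustness
when a minority (or non-modal) subset of instruments is invalid. The
primary estimate follows the usual reporting rule: Egger when the
intercept test is significant, random-effects IVW when Q is, fixed
effects otherwise. Binary-outcome effects are reported as odds ratios,
OR = exp(β) with 95% CI exp(β ± 1.96·se).

For mediation, with β_A the univariable MR effect of exposure on
mediator and β_B the mediator's *direct* effect on the outcome from a
two-exposure multivariable MR model:

    β_M  = β_A · β_B
    SE_M = sqrt(β_A²·SE_B² + β_B²·SE_A² + SE_A²·SE_B²)     (Aroian)

Mediation is **complete** when both path legs are significant but the
direct exposure→outcome effect β_C′ is not, **partial** when all three
are. The proportion mediated is |β_M/β_C′|·100% when β_M and β_C′ have
opposite signs (counteracting paths, direct-effect denominator) and
|β_M/β_C|·100% otherwise (total-effect denominator).

## Worked example

`examples/mediation_workflow.py` simulates a causal chain
exposure →(0.3)→ mediator →(0.2)→ outcome with direct effect 0.1 — so
the true total effect is 0.16 and the true mediated effect 0.06 — and
runs the full workflow:

```
truth: total = 0.160, mediated = 0.060, direct = 0.100

exposure->mediator (univariable MR): beta_A = 0.305 (se 0.007)
mediator->outcome direct (MVMR):     beta_B = 0.199 (se 0.005)
exposure->outcome total:             beta_C = 0.168
exposure->outcome direct (MVMR):     beta_C' = 0.107 (p = 5.54e-56)

mediation effect beta_M = beta_A*beta_B = 0.061 [0.057, 0.064]
classification: partial | proportion mediated: 36.0% (denominator: total effect)
```

Both path legs and the direct effect are significant, so the model is a
partial mediation; the product 0.061 recovers the simulated indirect
effect, and 36% of the total effect flows through the mediator.

`examples/published_tables.py` runs the same arithmetic on the four
published mediation models that ship with the package (effects and 95%
CIs transcribed from the source tables):

```
body fat percentage -> phenylalanine                       beta_M = +0.028 [-0.000, 0.056]  complete
body fat percentage -> free cholesterol to total-lipids ra beta_M = +0.014 [-0.000, 0.028]  complete
body fat percentage -> ratio of linoleic acid to total fat beta_M = -0.042 [-0.081, -0.004]  partial, 25.00% of the direct effect
obesity and other hyperalimentation -> phenylalanine       beta_M = +0.006 [-0.002, 0.014]  partial, 7.59% of the direct effect
```

The other examples cover the univariable estimator suite
(`univariable_mr.py`) and the sensitivity diagnostics
(`sensitivity_diagnostics.py`).

## Scope

Real cohort summary statistics (UK Biobank / FinnGen / IEU OpenGWAS
downloads) are deliberately out of scope: the package consumes any
tab/comma-delimited summary table with IEU-flavoured headers, and its
tests run entirely on the built-in simulator and the transcribed
published tables. Rendering of forest/scatter/funnel plots is left to
the caller; every diagnostic returns a plot-ready table instead.
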