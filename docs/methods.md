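# Methods

This note records the statistical model the package implements, the
defaults and the numerical conventions, and what the synthetic-data
validation does and does not establish.

## Causal model and estimators

The package operates on the standard two-sample MR setting: per-SNP
effect estimates for exposure and outcome come from non-overlapping
cohorts, so their sampling errors are independent. A valid instrument
must be (i) associated with the exposure, (ii) independent of
confounders, and (iii) affect the outcome only through the exposure
(exclusion restriction). Instruments are selected at p < 5e-8 (5e-6 for
reverse-direction analyses) and greedily clumped — candidates walked by
ascending p, kept unless r² ≥ 0.001 with a kept SNP or, when only
positions are known, within 10,000 kb of one. No LD reference panel is
bundled: with neither an r² matrix nor positions the package assumes
independence and says so loudly, which is exact for the built-in
simulator (independent biallelic loci) and wrong for real genotype data,
where the caller must supply LD information.

Harmonization aligns every outcome record to the exposure's effect
allele: swapped orientations flip the outcome beta and reflect its
allele frequency, complementary-strand records are complemented first,
and palindromic SNPs (A/T, C/G) follow a policy — default `infer`, which
uses the allele frequencies when both lie outside the 0.42–0.58
ambiguity window and drops the SNP otherwise (`keep` and `drop` are
available). Frequencies are optional; without them palindromic SNPs are
dropped under `infer` and this is logged.

Estimators (all consuming the harmonized set):

* **IVW** — zero-intercept weighted regression with weights 1/se_out²;
  fixed-effects SE from the weighted least-squares formula with residual
  scale pinned at 1; random effects are multiplicative, inflating the SE
  by √max(1, Q/df). Chosen over additive random effects because it needs
  no extra tuning parameter and reduces to fixed effects exactly when
  Q ≤ df. p-values are normal-based.
* **MR-Egger** — the same regression with a free intercept after
  orienting all SNPs to non-negative exposure effect; slope = causal
  effect, intercept = mean directional pleiotropy. Residual scale is
  floored at 1; inference is t-based with df = nsnp − 2.
* **Weighted median** — the weighted 50th percentile of the Wald ratios
  (weights 1/se_ratio²), linearly interpolated across the midpoint
  cumulative normalized weights; SE from a seeded parametric bootstrap
  (ratios perturbed by their SEs, default 1000 draws).
* **Simple/weighted mode** — argmax of a normal-kernel density over the
  Wald ratios, bandwidth = φ × the modified Silverman rule
  0.9·min(sd, mad)·n^(−1/5) with φ = 1 by default; the density is
  evaluated on a fixed grid of 4097 points spanning the ratio range
  extended by three bandwidths, making the estimate exactly reproducible;
  SE by seeded bootstrap.

Wald-ratio SEs use the first-order delta approximation se_out/|β_exp|
(outcome noise only); the second-order variant adding the exposure-noise
term is available behind a flag. The primary-estimate rule is: Egger if
the intercept test has p < 0.05; else random-effects IVW if Cochran Q
has p < 0.05; else fixed-effects IVW. The decision is recorded in the
run manifest.

## Diagnostics

Cochran's Q is computed about the fixed-effects IVW estimate with
df = nsnp − 1 (an Egger variant about the Egger fit with df = nsnp − 2
is exposed); I² = max(0, (Q − df)/Q)·100 with bands none (= 0), mild
(0–25], moderate (25–50], high (> 50) — the boundaries are closed on the
right, a convention fixed here because verbal range definitions overlap
at the edges. Leave-one-out refits IVW without each SNP and flags an
exclusion that flips the sign or exits the full-set 95% CI. The funnel
table pairs each Wald ratio with its precision 1/se. The Steiger
directionality test computes instrument-set variance explained per trait
via r²ⱼ = t²ⱼ/(t²ⱼ + n − 2) (the t-statistic transform is the default
because it needs no allele frequencies; the 2·eaf(1−eaf)·β² variant is a
flag), compares the Fisher-z transformed correlations with a two-sample
z-test, and declares the direction correct when the exposure r² exceeds
the outcome r².

## Multivariable MR and mediation

The multivariable design takes the union of each exposure's instruments,
re-clumps the pooled list, aligns every trait to a common effect allele
and drops SNPs missing from any trait. The fit is a zero-intercept
weighted multiple regression (weights 1/se_out²); SEs are inflated
multiplicatively when the model Q (df = nsnp − k) is significant;
p-values are t-based with df = nsnp − k. Per-exposure instrument counts
are bookkept by origin — each design SNP is attributed to the exposure
whose list it came from — which is why the reported nSNP differs between
exposures sharing one design. An identically zero exposure column yields
a zero estimate with infinite SE rather than an error; genuine rank
deficiency raises a collinearity error naming the exposures.

Mediation combines β_A (exposure→mediator, univariable primary) with
β_B (mediator→outcome direct effect from the two-exposure MVMR):
β_M = β_A·β_B with the Aroian SE
sqrt(β_A²SE_B² + β_B²SE_A² + SE_A²SE_B²) — the product-of-coefficients
variant whose third term makes it exact for the product of two
independent normals; the simpler Sobel form omits that term and
understates the SE when both legs are noisy. The workflow gates each
candidate mediator on significance of both path legs (α = 0.05) before
fitting MVMR, classifies complete/partial/none from the leg and
direct-effect p-values, and computes the proportion mediated with the
sign-dependent denominator rule (opposite signs of β_M and β_C′ →
direct-effect denominator, else total-effect). Display rounding follows
the published tables: effects to 3 decimals, proportions to 2.

No multiple-testing correction is applied by default — single-test
significance at p < 0.05 mirrors the workflow the package reproduces — 
but a Benjamini–Hochberg flag exists for reuse on wide metabolite
screens.

## Synthetic data

The generator emits GWAS summary tables directly at the summary level:
truth plus Gaussian noise with the analytic SE 1/sqrt(2·maf(1−maf)·n),
independent across the three traits. The causal chain is
exposure →(β_A)→ mediator →(β_B)→ outcome with direct effect β_direct;
exposure instruments therefore carry (β_direct + β_A·β_B)·γⱼ on the
outcome. Mediator-specific instruments are included because a chain-only
design makes the exposure and mediator beta columns proportional in
truth and the mediator's direct effect unidentifiable in MVMR;
outcome-specific instruments (off by default) give reverse-direction
analyses something to select.

Defaults encode the study conditions the package targets: 200 exposure
instruments and 30 mediator instruments (the order of the source
cohorts' panel sizes), GWAS sample sizes 330k/115k/218k, MAF uniform on
(0.05, 0.5), and panel variance shares of 0.20 (0.05 for the outcome's
own panel) — strong post-selection panels with mean per-SNP F in the
hundreds, as appropriate for genome-wide-significant metabolite loci.
Per-SNP variance contributions follow a shifted exponential
(0.25 + Exp(0.75), normalized): heterogeneous strengths are both
realistic and necessary for Egger-type regressions to be identified (a
panel of near-equal strengths has almost no spread in the regressor and
dilutes the Egger slope into a spurious intercept), while the floor
reflects that a real instrument panel contains no sub-significant
loci — simulating such loci and then re-selecting at 5e-8 induces a
winner's-curse attenuation that real post-selection panels do not have.
Effect alleles are coded as the exposure-increasing allele (all γⱼ > 0),
the convention under which directional pleiotropy has a well-defined
sign; emitted records are randomly orientation- and strand-shuffled,
with ~10% palindromic allele pairs, to exercise harmonization.
Horizontal pleiotropy, when enabled, acts directly on the outcome
(balanced: mean 0; directional: configurable mean), independent of
instrument strength, so the InSIDE condition holds and the Egger
intercept estimates its mean. `het_sd` adds per-SNP outcome-effect
dispersion for dialing in heterogeneity. Binary-trait log-odds effects
are treated as linear-scale betas; the logistic non-collapsibility
subtlety is out of scope.

What passing on this generator shows — and does not. It validates the
estimators, diagnostics and mediation arithmetic under exactly the
assumptions two-sample MR makes (independent instruments, independent
samples, additive effects). It does not exercise LD between instruments,
sample overlap, selection on the outcome, non-collapsibility of odds
ratios, or instrument-strength winner's curse — all present to some
degree in real cohort data.

## Validation choices and known limitations

* Parameter-recovery checks run 200 replicates at m = 100 instruments
  and n = 100k per cohort (the null calibration uses 1000); sizes keep
  the full suite around a minute on one CPU while the Monte-Carlo SE of
  the replicate mean resolves sub-percent biases.
* Plain IVW and MVMR carry the known weak-instrument (errors-in-
  variables) dilution of order m/(n·share) — here ≲1% of the effect at
  mean F ≈ 200–300. The recovery checks resolve exactly this order, so
  they sit close to their bounds; a debiased-IVW estimator would remove
  the dilution but is deliberately not part of this package's scope.
* The heterogeneity-null validation uses 500 instruments because the
  truncated I² statistic has a positive small-sample bias of roughly
  sqrt(2/(π·df)) even with no true heterogeneity (~5.7% at df = 99,
  ~4% at df = 199); at df = 499 the bias is well clear of the 5%
  validation line, so the check isolates the generator's heterogeneity
  dial rather than I²'s finite-df behaviour.
* Greedy clumping is order-exact but O(kept × candidates) with pairwise
  lookups — fine for panels of hundreds, not meant for genome-wide
  candidate lists.
* The published-table fixtures carry printed (rounded) effects and CIs;
  reconstruction tests therefore use tolerances of half a printed unit
  (0.0005–0.001), not machine precision.
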