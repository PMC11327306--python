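# Methods

## The statistical model

For each autosomal gene *g* in one dataset, individuals are coded
`carrier = 1` if they carry at least one qualifying rare LOF variant in *g*
(an indicator, never a count) and the disease model

    logit P(case_i) = alpha + X_i' gamma + beta * carrier_i(g)

is fit by maximum likelihood (Newton/IRLS; deviance tolerance 1e-8, at most
50 iterations). The reported two-sided P comes from the likelihood-ratio
statistic `chi2 = 2 (ll_full - ll_null)` against chi-squared with 1 df,
where the null model omits the carrier term. The covariate matrix `X` is
whatever the dataset requires (sex, age, principal components, batch
indicators, ...); it is configuration, not code — real analyses of
different cohorts adjust for different sets, and the pipeline accepts an
arbitrary per-dataset matrix through the phenotype table. Since the null
model does not depend on the gene, a scan fits it once per dataset and
reuses its log-likelihood for every gene.

**Genomic control.** Residual inflation from stratification and cryptic
relatedness is corrected by dividing the LRT chi-squared by a per-dataset
intercept `lambda` (an LD-score-regression intercept, e.g. 1.14 for a
founder population with extensive relatedness, 1.00 where no inflation is
seen). Intercept *estimation* is out of scope: `lambda` is a configuration
input. The adjustment must also propagate to meta-analysis, which consumes
(beta, se) rather than chi-squared; we rescale `se_adj = se * sqrt(lambda)`
so that the Wald z implied by the meta inputs matches the adjusted
per-dataset P. This propagation rule is a documented choice — dividing
chi-squared and inflating the variance by `lambda` are the same operation
on the Wald scale — and `lambda = 1` leaves everything untouched.

**Sparse genes and separation.** Likelihood asymptotics fail when carriers
are few or fall entirely in one outcome class. Genes with fewer than 10
carriers (the default `sparse_threshold`; a cohort analysed in the
motivating study with 6 carriers used the exact test), and genes whose
logistic fit separates (detected as all carriers in one class, a
non-converged fit, or |beta| > 15), are analysed with a two-sided Fisher's
exact test using the probability-mass definition of "two-sided": the P sums
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed the observed table's. The reported odds ratio
for this path is the sample cross-product ratio (infinite when a
denominator cell is empty), with a conditional exact confidence interval —
the convention of R's `fisher.test`, which reproduces published intervals
for this path. When such a gene enters meta-analysis, its log-OR standard
error is recovered from the exact CI as
`se = (ln hi - ln lo) / (2 * 1.959964)`; this treats an exact interval as
if it were Wald, a deliberate approximation that lets sparse cohorts
contribute their (small) weight to the pooled estimate.

**Meta-analysis.** Fixed-effects inverse-variance weighting:
`w_i = 1/se_i^2`, `beta_pooled = sum(w b)/sum(w)`,
`se_pooled = 1/sqrt(sum(w))`, two-sided normal P. Heterogeneity uses
Cochran's Q, `sum w_i (beta_i - beta_pooled)^2`, which under the Gaussian
summary-data likelihood is algebraically twice the log-likelihood gain of
per-study free effects over a common effect — i.e. an LRT with k−1 df (the
test suite verifies the identity numerically to 1e-9). No small-k
correction is applied (k is 2–3 in the motivating design) and no
random-effects pooled estimate is produced: the random-effects model serves
only as the heterogeneity alternative. Datasets with no usable (beta, se)
pair for a gene are dropped from that gene's pooling with a logged note.

## Variant QC

The slope diagnostic regresses observed alternate-allele read counts on
their expectation under the called genotype, `x = depth * g / 2`, through
the origin, pooled over genotype classes: `slope = sum(xy)/sum(x^2)`. A
clean variant has slope 1 ("identity line"); artifact or somatic signal
shows fewer alternate reads than the genotype predicts and drags the slope
down. Variants with slope < 0.5 are filtered (slope exactly 0.5 passes —
the filter is a strict "less than"), as are variants with caller
true-positive score AAscore ≤ 0.8 (strict "greater than" to pass). Whether
the original diagnostic fit one regression per genotype class or pooled is
not specified anywhere we could check; the pooled through-origin form is
the simplest model for which "slope 1, intercept 0" is exactly the ideal,
and is our documented interpretation. Homozygous-reference records carry no
expected signal under this model and are excluded; a variant with no
genotype-positive evidence cannot be assessed and fails conservatively.

## Qualifying-variant rules

LOF means a predicted consequence of start-lost, stop-gain, stop-lost,
splice donor, splice acceptor or frameshift (ampersand-joined VEP multi-term
strings qualify if any component does; unrecognised terms log a warning and
count as non-LOF). Qualifying additionally requires MAF < 0.1% (strict),
LOFTEE `HC`, and a passing QC record. MAF is the sample allele frequency
over non-missing genotypes of the loaded dataset — no external reference
panel is consulted. Missing genotypes count as non-carrier (conservative
for a rarity indicator). Multi-allelic VCF records are rejected rather than
silently mangled, because consequence and frequency semantics are per
alternate allele; decompose upstream. LOF-class variants lacking a LOFTEE
tag are excluded by default with a warning (switchable).

## The synthetic cohort generator

The generator produces data for which the pipeline's model is the true
generative process. Genotypes are Hardy-Weinberg draws `Binomial(2, maf)`
per site with MAF uniform in a configured range capped at 0.005 (rare, but
able to straddle the 0.1% filter); no linkage disequilibrium, relatedness
or X chromosome. The disease model is
`logit = intercept + sum_g beta_g * carrier_g + covariate effects`, where
`carrier_g` indicates ≥ 1 alternate allele at the gene's clean LOF sites,
and the intercept is solved by bisection so the expected case fraction
matches `n_cases/(n_cases+n_controls)` — case-control studies are
fixed-size designs, not prospective samples, so realised counts vary
binomially around the targets. Default covariates are a binary sex
indicator (P = 0.5, logit effect 0.4) and a standard-normal age z-score
(effect 0.8): minimal stand-ins chosen to make covariate adjustment matter
without dominating the signal.

Read evidence per site draws `depth ~ Poisson(depth_mean)` (default 38, a
typical WGS coverage) and, for clean sites,
`alt ~ Binomial(depth, g/2 shrunk toward error_rate)`, so heterozygotes
average depth/2 and the fitted slope is ~1. Spurious sites emit alternate
reads at a fixed 0.1 fraction of depth regardless of genotype, giving a
fitted heterozygote slope near 0.2 — safely below the 0.5 filter. The real
failure mode behind slope-violating variants is not described beyond the
diagnostic itself; this sub-slope model is a stand-in chosen to produce the
diagnostic's signature, and is flagged as such. Hom-ref read-evidence
records carry no slope information and are down-sampled (default 50 per
site) to keep large simulations tractable.

What the simulator does *not* emulate — LD, relatedness and population
structure, imputation uncertainty, variant-calling error beyond the
artifact model, covariate distributions of real biobanks — bounds what
passing tests show: they validate the statistical machinery under its own
assumptions, not robustness to real-data violations of them.

## Validation studies and problem sizes

`lofburden.validation` packages three operating-characteristic studies,
run by the test suite and the reproduction script:

* **Null calibration**: 2,000 null genes (3 sites each, MAF 0.35%, so
  ~2% carrier frequency ≈ 80 carriers per gene in a 4,000-individual
  cohort — comfortably inside the chi-squared asymptotic regime), with sex
  and age acting on the disease model and adjusted for. The type-I error at
  alpha = 0.05 is checked against the exact binomial 99% interval.
* **Parameter recovery**: 200 replicates of one causal gene with true
  OR 7.3 at ~0.1% carrier frequency (10 sites, per-site MAF solved from
  `1-(1-m)^(2V) = 0.001`) in 25,000 cases / 25,000 controls; the reported
  95% CI must cover the truth in ≥ 93% of replicates. The point estimate
  shows the expected mild upward small-sample bias of logistic ML at ~50
  carriers; coverage, the inferential guarantee, is what is asserted.
* **QC discrimination**: 200 clean and 200 artifact sites with 40
  heterozygotes at depth 30; ≥ 95% of clean sites must pass and ≥ 95% of
  artifact sites fail the slope filter.

These sizes keep the whole suite to well under a minute of simulation on
one core while leaving Monte-Carlo error small relative to every asserted
margin.

## Numerical choices and edge cases

* z-quantile for 95% intervals fixed at 1.959964 so CI round-trips
  (`ci_to_se` after `wald_ci`) are exact.
* `genomic_control_adjust` accepts intercepts below 1 with a warning but
  never rescales statistics upward; non-positive intercepts are errors.
* Fisher two-sided mass comparison uses relative tolerance 1e-7 when
  deciding which tables are "at most as probable" (inherited from the
  standard implementation; the enumeration oracle in the tests applies the
  same rule).
* Degenerate 2×2 margins (no carriers anywhere) give P = 1 with an
  undefined odds ratio rather than an exception.
* Zero-carrier genes are skipped with a structured log reason, as are
  variants removed by each filter (`qc_slope`, `qc_aascore`, `maf`,
  `loftee`, `non_autosomal`).
* The LRT statistic is floored at 0 (IRLS round-off can make it
  infinitesimally negative).
* Report display: two significant figures for CVFs and thresholds, one
  decimal for odds ratios ≥ 1.

## Known limitations

* The carrier indicator ignores allelic series and dosage; burden weighting
  schemes (or variance-component tests) are out of scope by design.
* The exact-CI-to-Wald-se conversion for sparse cohorts understates the
  asymmetry of the exact interval; with the tiny weights such cohorts get,
  the pooled estimate is insensitive to this.
* Genomic-control propagation to the meta SE is one defensible convention;
  analyses that adjust only the P values will differ slightly for
  `lambda != 1`.
* Age-at-onset comparisons use Welch's unequal-variance t test — a
  documented choice, since summary statistics alone cannot identify which
  exact test produced a published onset P.
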