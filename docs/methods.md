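# Methods

## Model

`xpoo` fits a conditional likelihood for X-linked parent-of-origin (PoO)
effects in case-parent triads. The complete data for one triad are a
*configuration*: the mother's ordered haplotype pair (transmitted,
untransmitted), the father's haplotype, and the child's sex. Under
Hardy–Weinberg equilibrium, random mating and Mendelian transmission, the
prior probability of a configuration is π(mt)·π(mu)·π(f) with a single
haplotype-frequency vector π shared by mothers and fathers; ordering the
mother's pair by transmission folds the 1/2 transmission probability into
the pair prior. Conditional on the child being affected, the probability of
a configuration is proportional to its prior times the child's penetrance
multiplier:

* girls: RRm(maternal haplotype) × RRf(paternal haplotype),
* boys: RR_B(maternal haplotype), with RR_B tied to the girls' parameters by
  the constraint RR_B = RRm·RRf (X-inactivation) or RR_B = RRm (no
  X-inactivation).

Baseline risks are sex-specific but cancel exactly in the per-sex
normalization, so they are parameters of the simulator only (defaults 0.4%
for girls, 0.5% for boys, purely documentary). Fathers of boys do not
transmit an X to their sons but are retained in the likelihood: their
genotypes inform π. The PoO measure is RRR = RRm/RRf per non-reference
haplotype.

Observed data are genotype dose vectors with arbitrary missingness and
unknown phase. The observed-data likelihood of a triad is the sum of
conditional configuration probabilities over all configurations compatible
with its observed doses; a fully missing triad contributes nothing. This is
the exact marginal the EM algorithm would maximize; we maximize it directly
(see below). Within a window of up to 4 SNPs all 2^w haplotypes over the
window are enumerated (configuration space K³ ≤ 4096) and no recombination
is assumed within the window.

Assumptions worth stating: HWE and random mating in the parental
generation (no frequency dispersion parameter); a multiplicative risk model
(a girl's double dose is the product RRm·RRf, never a free parameter); one
affected child per family; triads with a heterozygous girl and both parents
missing are marginalized over all phase-and-parent completions.

## Estimation

Parameters are the frequency logits (softmax with the reference haplotype as
baseline), and log RRm, log RRf for each free haplotype. The reference
haplotype is the most frequent (ties broken lexicographically by allele
string). Haplotypes whose prefit frequency falls below
`rare_haplotype_min_freq` (default 0.01) keep their frequency parameters but
have their relative risks fixed at the reference level and are excluded from
the test's degrees of freedom — the pooling exists for numerical stability
of 4-SNP windows, and fixing the risks achieves it without destroying the
genotype-compatibility structure of the configuration space.

The likelihood is maximized by BFGS with an analytic gradient (verified
against central differences to 1e-7). Initialization: allele-count frequency
estimates for single SNPs or a frequencies-only ML prefit for multi-SNP
windows, all log RR = 0; the free fit is warm-started from the null fit.
Optional seeded random restarts guard multimodality in 4-SNP windows.
Convergence uses gradient norm < 1e-8 with at most 1000 iterations. Windows
are refused when monomorphic, or with fewer than `min_informative` (default
10) informative triads.

Inference:

* per-haplotype CIs and p-values are Wald on the log scale, with standard
  errors from the inverse observed information (central-difference Hessian of
  the log-likelihood, step 1e-5); log RRR and log RR_B use the delta method
  (they are linear in the parameters);
* the window-level PoO test is a likelihood-ratio test of RRR = 1 for all
  free haplotypes against the free model, with RRm = RRf still free under
  the null so the test isolates the transmission asymmetry rather than the
  overall allele effect; the statistic is referred to chi-square with df =
  number of free haplotypes. A Wald version of the window test is reported
  alongside (`wald_window_p`); the LRT is the default `window_p`.

`girls_only` fits the same parameters on female-child triads alone; RR_B is
then undefined and reported as NaN.

## Quality control

The QC cascade masks members (rather than deleting triads where possible):
individuals with more than 10% missing genotypes are masked (a failing child
drops its triad, since the likelihood conditions on the affected child);
X-linked Mendelian-inconsistent triads are masked per SNP with the per-SNP
error counts recorded first; then SNPs are filtered on missingness (> 1%),
MAF (< 0.01, hemizygosity-aware counting: females contribute two alleles,
males one) and the recorded Mendelian error counts (> 30). Masking before
the SNP statistics makes the cascade idempotent. The Mendelian verdict for a
triad with missing members enumerates all completions: consistent only if
every completion is, inconsistent only if none is, otherwise unknown. The
Hardy–Weinberg exact test (reported per SNP) uses the mothers only: fathers
are hemizygous and affected children are ascertained, so mothers are the
only members with a defensible HWE null; the test conditions on allele
counts and sums the probabilities of all heterozygote counts no more
probable than the observed one.

## Scans and FDR

A scan fits every consecutive window of a fixed size in map order. Windows
that cannot be fitted are emitted with a status flag and excluded from the
FDR family; q-values are computed per scan (one model × one sex restriction
is one testing family). Storey q-values use the λ-grid estimate of the null
proportion π₀ (λ = 0.05…0.95, step 0.05) smoothed by a natural cubic spline
with effective df = 3 (the penalty is solved by bisection on the smoother
trace; it reproduces R's `smooth.spline(df = 3)` to five decimals) and
evaluated at λ = 0.95, clamped to (0, 1]; with fewer than 100 p-values the
conservative π₀ = 1 is used. Manhattan output reports −log₁₀(p) against
position with a 10⁻⁴ reference-line constant attached as metadata.

## Simulator

`simulate_triads` draws configurations *exactly* from the conditional-on-
affected distribution (categorical sampling over the K³ configurations per
sex) — no rejection loop and no absolute-risk bookkeeping, because the
conditional model is precisely what the likelihood sees. Child sex is
Bernoulli(`prop_female`); parental genotypes are masked independently at
`missing_rate_parent` (children stay observed by default, matching the way
incomplete triads arise in practice). Per-replicate randomness is spawned
from the master seed with counter-based spawn keys, so grids are
reproducible and order-independent. Defaults encode the study conditions
used throughout the tests: MAF 0.2, 600 triads (300 for girls-only
analyses), equal sex split, α = 0.05, 1000 replicates for power.

What the simulator does *not* emulate: linkage disequilibrium between
windows (SNPs in `simulate_chromosome` are in linkage equilibrium),
genotyping error, population stratification, or multiple affected children
per family. Passing tests therefore demonstrate correctness of the
estimator and calibration under the model's own sampling assumptions, not
robustness to those real-data complications.

## Numerical and design choices

* Direct maximization instead of EM: the observed-data likelihood and its
  analytic gradient are cheap at these problem sizes, and BFGS converges in
  a handful of iterations; EM's monotone but slow updates buy nothing here.
* The conditional sampler, the likelihood and the analytic power
  approximation used in tests are three independent routes to the same
  distribution; tests cross-check them (goodness of fit of 100k sampled
  configurations; grid-search oracle equivalence of the optimizer to 1e-3
  log-likelihood units on ≤ 60-triad problems).
* Power is the fraction of replicates with window p < α; failed replicate
  fits are excluded from the denominator and reported (warned above 1%).

## Known limitations

* The chi-square reference for the window test is asymptotic. At 300 triads
  per window its far tail is about 10% liberal (measured over 4000 null
  fits: P(p < 0.01) = 0.012), and the discreteness of the statistic near
  zero depletes p-values near 1, which biases the λ-grid π₀ estimate
  downward. As a consequence the realized false-discovery proportion at
  q ≤ 0.2 in the 300-triad mixture simulation averages ≈ 21%, just above
  the nominal 20%; at 600 triads per window the tail is calibrated
  (empirical type-I error 0.049 at α = 0.05) and the q-value machinery fed
  uniform null p-values averages FDP 0.19.
* The Wald power approximation from the expected information is accurate at
  moderate power but undershoots in the saturating regime (the log-RRR
  estimator is skewed at large effects); tests compare against it only
  where the asymptotics hold.
* Problem sizes in the test suite (hundreds to a few thousand triads,
  thousands of windows, 20 FDR replicates) were chosen as the smallest
  sizes at which the Monte-Carlo error bands in the assertions are
  meaningful.
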