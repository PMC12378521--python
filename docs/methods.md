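# Methods

`gpeval` benchmarks genomic-prediction designs for a single quantitative
trait measured on one genotyped population — the situation of an
aquaculture breeding nucleus, where a few hundred fish are resequenced,
body weight is recorded once, and the breeder must choose a marker panel,
a prediction model, and a training design before committing to a
genotyping budget. Everything below is implemented against simulated data
so that every claim the test suite makes is checkable against a known
truth.

## The prediction model family

All six models regress phenotype on markers, `y = mu + X beta + e`, with
genotypes coded 0/1/2 as minor-allele counts and `e ~ N(0, I sigma_e2)`.

**GBLUP.** Marker effects are exchangeable Gaussians, which is equivalent
to a linear mixed model `y = mu + u + e`, `u ~ N(0, G sigma_g2)`, where
`G = WW' / (2 sum p_j (1 - p_j))` is the VanRaden genomic relationship
matrix built from allele-frequency-centered genotypes `W`. Variance
components are estimated by REML: one eigendecomposition of `G`, then a
bounded Brent search (tolerance 1e-8) over the log variance ratio
`log(sigma_g2 / sigma_e2)` on [-10, 10]. Training GEBVs come from the
mixed-model solution `u = sigma_g2 G V^{-1}(y - mu)`; validation GEBVs
from kinship regression `u_test = G_test,train G_train,train^{-1} u_train`
with a relative ridge of 1e-8 on the training block, which G needs because
column centering makes the all-ones vector an exact null direction. GBLUP
is algebraically ridge regression on centered markers with penalty
`sigma_e2 * denom / sigma_g2`; the test suite asserts both identities
numerically.

**Bayesian alphabet.** BayesA (scaled-t prior via per-marker variances),
BayesB (spike-and-slab with a scaled-t slab), BayesC (spike-and-slab with
a common slab variance), Bayesian LASSO (double-exponential prior via the
exponential scale mixture) and Bayesian ridge regression (common Gaussian
prior) differ only in the prior on `beta`. All are fitted by a single-site
Gibbs sampler with residual updating, so one iteration costs O(n p).
Posterior summaries are running means over post-burn-in draws (thin 1);
full traces are available behind `store_traces` for diagnostics.

Hyperpriors are scaled-inverse-chi-square with 5 degrees of freedom.
Scales are set so the prior *mode* of each variance allocates half of the
phenotypic variance to the markers and half to the residual (prior
R² = 0.5) — the convention of the standard whole-genome-regression
software this mirrors. For the spike-and-slab models the slab scale is
inflated by `1/(1 - pi0)` so the expected genetic variance is preserved
when only a fraction `1 - pi0` of markers is active; `pi0` defaults to
0.95 and is held fixed rather than sampled. The Bayesian LASSO
regularization parameter is likewise fixed from the prior-R² rule,
`lambda^2 = 2 (1 - R2) MSx / R2` with `MSx` the summed marker variances,
instead of being given its own hyperprior: fully specified and
reproducible, at the cost of not adapting `lambda` to the data. MCMC
defaults are 10,000 iterations with 2,000 burn-in.

Markers are always centered by **training-fold** allele frequencies;
prediction applies the same centering to validation genotypes. This is
the leakage boundary: no validation phenotype or frequency can reach the
fit.

## The association scan

The GWAS model is `y = Xb + Zu + e` with `u ~ N(0, G sigma_g2)`. Variance
components are estimated once on the null (no-marker) model and reused for
every marker — the standard two-stage approximation. Each marker is then
tested by generalized least squares in the whitened model; the residual
variance of the Wald statistic is re-estimated per marker from the
marker-included regression (denominator `n - q - 1`), and the statistic is
referred to chi-square with 1 df. With identity kinship this reduces
exactly to the ordinary-least-squares large-sample z-test, which is how
the scan is validated. An exact per-marker REML refit is deliberately not
implemented: the only downstream consumer is the ascending-p *ranking*
that drives marker preselection, for which the two-stage approximation is
adequate and orders of magnitude faster — it must rerun inside every
cross-validation fold. Monomorphic markers get `beta = 0, p = 1` and a
flag rather than being dropped, keeping the ranking total. Fixed effects
default to an intercept; user columns are accepted but no automatic
structure correction (e.g. PCs) is added.

## Marker selection

Three strategies produce a `k`-marker panel: GWAS ranking (smallest p
first, ties broken by genome coordinate), even spacing, and uniform
random sampling. Even spacing works on SNP *index*, not bp distance:
chromosomes receive quotas proportional to their marker counts
(largest-remainder rounding, ties to chromosome order), each chromosome's
index range is cut into quota equal segments, and the lower-middle marker
of each segment is taken. Index-based segmentation guarantees every
segment contains a marker; bp-based segmentation does not. The selection
functions are pure: `evenly` is a function of `(layout, k)` only, and
`random` is reproducible from its seed.

## Cross-validation and the inflation audit

`run_cv` performs k-fold cross-validation (default five folds, repeated
five times, simple random fold assignment). In the honest `cv_gwas` mode
the association scan is refitted on the training individuals of every
fold before selecting markers; in the `all_gwas` audit mode markers are
ranked once by a whole-population scan that includes the validation
individuals. The audit arm is retained deliberately: selecting features
on data that includes the test set is a common and subtle error, and on a
pure-noise trait it manufactures large apparent accuracy while the honest
arm stays at zero. Phenotype-free strategies (evenly, random) are selected
once per repeat — random with a fresh per-repeat seed — since no
phenotype can leak through them. Accuracy is the Pearson correlation
between predicted GEBVs and masked validation phenotypes, reported as
mean ± sample sd over the fold-by-repeat grid with no Fisher transform,
and a degenerate validation set yields a missing value, never a zero.

One caveat the audit tests respect: all fold-results of one experiment
share a single phenotype realization, so they are positively correlated
and the naive CI over 25 fold-values is narrower than the truth. The
inflation contrast is therefore checked as a *paired* comparison
(all_gwas minus cv_gwas per fold), which differences that shared noise
out.

The training-size sweep freezes one validation set (default 138
individuals) and samples training subsets of each requested size from the
remainder, five replicates per cell, GBLUP only. The density sweep reuses
`run_cv` across a density grid; the cost/accuracy report names the
smallest density whose mean accuracy is within one sd (at the maximum) of
the best mean — a deliberately simple elbow rule.

## The simulator

`simulate_genotypes` draws ancestral minor-allele frequencies from a
chosen spectrum (uniform(0.05, 0.5) by default), optionally differentiates
subpopulations by the Balding–Nichols Beta construction at a chosen Fst,
and generates haplotypes from a first-order latent-Gaussian process along
each chromosome: adjacent markers at distance `d` bp have latent
correlation `exp(-ld_decay * d)`, and two haplotypes are summed per
diploid individual. One parameter reproduces the monotone LD decay that
genomic-prediction theory assumes, at desk-scale cost. Columns are
re-oriented to the realized minor allele; exact 0.5 ties keep the
simulated orientation.

`simulate_phenotypes` places QTLs on typed markers (without replacement;
optionally hidden from the returned panel), draws effects from a gaussian,
laplace, point-normal, or equal-magnitude/random-sign distribution, and
scales the genetic and residual parts so the expected narrow-sense
heritability equals the target; the realized ratio of the actual draw is
recorded. The default trait scale mimics juvenile body weight of a farmed
marine fish (mean 655.64 g, sd 213.15 g). The `equal` distribution exists
for designed power checks: with gaussian effects the event "every planted
QTL is detectable" has irreducible failure probability because an effect
can be drawn arbitrarily close to zero, so recovery guarantees are only
meaningful when each QTL carries a fixed variance share.

What the simulator does *not* emulate: pedigree and family structure,
selection over generations, genotyping error and allelic dropout,
non-additive (dominance/epistatic) variance, and the long-range admixture
LD of real breeding populations. Passing tests therefore demonstrate the
*machinery* — estimators recover what the generative model planted, and
leakage is detected where it is planted — not that any particular
accuracy level will transfer to a real population.

## Quality control and I/O

Genotypes travel as VCF v4.2 (GT only; indels and non-biallelic records
are dropped on read), phenotypes as `sample_id \t value` TSV, panels as
`chrom:pos:id` lists. QC applies, in order: individuals with marker call
rate < 0.9, then SNPs with genotype call rate < 0.9, then SNPs with
MAF < 0.05 — each rule strict (`== threshold` survives), each computed on
the survivors of the previous rule, MAF on non-missing calls. Residual
missingness is imputed with the per-SNP mean genotype rounded to the
nearest of {0, 1, 2} (exact .5 rounds half-to-even, deterministically).
Haplotype-phasing imputation is out of scope; users of real data should
pre-impute upstream, and simulated data are complete.

## Numerical choices and check sizes

- REML: eigenvalues clipped at 0; non-PSD kinship beyond -1e-6 relative
  is an error instructing an explicit ridge. Boundary candidates of the
  ratio search are checked explicitly.
- Kinship regression ridge: 1e-8 × mean diagonal.
- Divergent (non-finite) MCMC variance draws abort with the iteration
  number and state magnitudes in the message.
- The verification suite runs at sizes chosen to finish on one CPU in a
  few minutes while leaving the checked effects far above their noise
  floors: 30×100 for linear-algebra identities, 20×50 × 10,000 iterations
  for the conjugate sampler check, n=300 / p=2000 (three pooled null
  traits) for scan calibration, n=800 × 10 replicates for heritability
  recovery, n=400 / p=20,000 for the inflation audit, and n=692 with a
  138-individual frozen validation set for the learning curve.

## Known limitations

- `pi0` is fixed, not sampled; misspecifying it biases BayesB/C shrinkage.
- The Bayesian LASSO's fixed `lambda` cannot adapt to unusual genetic
  architectures.
- The scan's two-stage variance approximation slightly miscalibrates
  p-values when a single marker explains a large variance share; the
  ranking is unaffected in practice.
- Fold assignment is unstratified; with strong population structure,
  cluster-aware folds (not implemented) would give more conservative
  accuracy estimates.
- Single trait, additive effects only.
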