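# Methods

`pmfmeth` reimplements, as a reusable and tested pipeline, a genome-wide
DNA-methylation analysis that discriminates prefibrotic primary myelofibrosis
(pre-PMF) patients with later fibrotic progression (FP) from patients with
stable disease (SD), using EPIC-style beta-value matrices as input. Because
the original bone-marrow cohort is not bundled, a synthetic-cohort generator
with fully known planted structure stands in for it; every pipeline stage is
validated against that ground truth.

## Data model

A cohort is a samples x probes matrix of beta-values
(beta = M/(M+U) per CpG, in [0, 1]; NaN marks missing measurements), matched
methylated/unmethylated intensity matrices, a detection p-value matrix, a
probe manifest (chromosome, 1-based position, Infinium design type I/II,
CpG-island relation, gene) and a sample sheet (group FP/SD, plate, age, sex,
optional clinical covariates). All linear modelling is done on M-values
(M = log2(beta/(1-beta)) with beta clamped to [1e-3, 1-1e-3]); effect sizes
are reported on the interpretable beta scale.

## Preprocessing

**Detection filtering.** Samples whose fraction of probes with detection
p > 0.1 exceeds 10% are excluded; afterwards probes failing in more than 5%
of the remaining samples are excluded. The p-threshold of 0.1 is the
array-QC convention for FFPE material; the sample and probe fractions are
exposed in the configuration. Surviving beta-values are not modified.

**BMIQ.** Type II Infinium probes read a compressed dynamic range relative
to type I. Per sample, a three-state beta mixture
(unmethylated/hemimethylated/methylated) is fitted by EM separately to each
design type (quantile-based initialisation, weighted method-of-moments
updates, log-likelihood tolerance 1e-5, at most 1000 iterations; assignment
ties break toward the lower-mean state). Type II probes in the outer states
are quantile-mapped onto the corresponding type I beta distribution; the
middle state is linearly rescaled between the mapped outer states. A final
isotonic pass over the sorted type II values removes state-boundary
artefacts, making the transform monotone by construction. Type I probes are
returned unchanged.

**ComBat.** Parametric empirical-Bayes batch correction on M-values: normal
priors on per-batch probe-wise location shifts, inverse-gamma priors on
scales, estimated by moments and solved by the standard fixed-point
iteration; the group (FP/SD) design is protected. A batch structure
confounded 1:1 with the protected covariate is rejected as inestimable.
Correction is applied only on the statistics/visualisation branch:
classification inputs are deliberately never batch corrected, so the
classifier can be applied to single new samples where no batch model exists.

**SVD confounder screen.** The top min(20, n_samples-1) left singular
vectors of the probe-centred beta matrix are tested against each sample
variable (Kruskal-Wallis for categorical, Spearman for numeric). Raw
p-values and BH-adjusted q-values across a variable's components are
reported; a variable is flagged when any q < 0.05. BH across the ~20
component tests is what keeps the null flag rate near the nominal 5% — raw
p < 0.05 over 20 components would flag noise variables most of the time.

## Differential methylation

**DMPs.** Per probe, a two-group contrast on M-values with moderated t:
residual variances are shrunk toward a common prior whose degrees of freedom
and scale come from moments matching on the log variances (trigamma
inversion; prior df capped at 100), t uses df = residual + prior df.
Zero-variance probes are floored at 1e-12 and flagged. q-values are
Benjamini-Hochberg; "differentially methylated" means q <= 0.1 — a purely
statistical definition with no delta-beta cutoff. With the shrinkage prior
df forced to 0 the statistic reduces exactly to the ordinary two-sample t.

**DMRs.** Bump hunting: probes are clustered so consecutive within-cluster
gaps are <= maxGap (default 250 bp); the per-probe coefficient is the
beta-scale group difference; candidate bumps are maximal same-sign runs with
|coefficient| above the 0.99 quantile of all |coefficients| (the quantile
reading of the "cutoff" parameter; an absolute-value cutoff would be an
alternative configuration). The bump statistic is the area (sum of
|coefficients|). The null distribution uses 250 seeded group-label
permutations with the original cutoff; p is the fraction of permutations
whose maximal bump area reaches the observed one (family-wise style, chosen
over pooled-area p-values because it stays well defined when permutations
produce few bumps, at the price of conservatism). Regions with BH q <= 0.05
are reported; BED exports are 0-based half-open, internal coordinates
1-based inclusive.

**Gene-set enrichment.** Genes with more probes are more likely to contain a
significant CpG by chance. Per term the p-value is a Wallenius noncentral
hypergeometric tail with odds equal to the ratio of mean probe counts inside
vs outside the term, reducing to the ordinary hypergeometric when probe
counts are uniform. Being a discrete exact test, the p-values are
super-uniform (conservative) under the null; the test suite checks the
one-sided bound rather than exact uniformity, which no discrete test can
attain.

**Clustering.** Heatmap ordering uses agglomerative clustering with centroid
linkage on Euclidean beta distance, separately for samples and probes, on
the top-N probes by p (ties by |t|, then probe id). Centroid linkage can
produce inversions; the tree is reported as-is.

## Panel selection and classification

Subsets of candidate CpGs are scored by tau^2 = 1 - Lambda with
Lambda = det(E)/det(T) (within-group over total scatter). For two groups
the general criterion tau^2 = 1 - Lambda^(1/l) has l = 1, so this is the
canonical two-class form. Lambda is computed by Cholesky-whitening T and
taking the product of the eigenvalues of L^-1 E L^-T, which lie in [0, 1];
this is numerically stable where the raw determinant ratio overflows for
large near-singular subsets. A ridge of 1e-6 x trace/k is added when T is
not positive definite.

The best subset of each size k is found exactly by branch and bound:
tau^2 never decreases when probes are added, so tau^2 of a partial selection
plus all remaining candidates bounds every completion; branches that cannot
beat the incumbent are pruned. The search result is therefore identical to
exhaustive enumeration (verified against an independent brute-force oracle).
Ties between equal-tau^2 subsets break lexicographically by probe id. The
candidate pool is the top 40 DMPs by p (the pool size is configuration; the
source study does not state its pool).

`minimal_panel` walks k = 1..k_max, fits a two-class LDA on each best
subset, and returns the smallest k with zero training misclassifications
(models needing fewer probes are preferred); if none separates, the k_max
model is returned flagged non-separating. LDA weights are
w ∝ Σ_pooled⁻¹ (μ_FP − μ_SD), scaled so the projected pooled within-group
variance is 1 and signed so the FP centroid projects negative on LD1. The
decision threshold is the posterior-equality point of the two equal-variance
Gaussians on LD1, shifted by the log prior ratio. Class probabilities come
from the same projected model; confidence bands are "high" at max
probability >= 0.95, else "low" (> 0.5). Cross-validation is stratified
five-fold, repeated, with subset selection redone inside every training fold
so no information leaks from held-out samples.

## Copy-number profiles

Combined intensity (methylated + unmethylated) is proportional to local copy
number. The median combined intensity of the query group (or a single
sample) is divided by the probe-wise median of the reference cohort; log2
ratios are recentred so the median autosomal ratio is zero (whole-genome
ploidy is unobservable on a single array). Segmentation is recursive binary
splitting per chromosome: split at the position maximising the two-sample
t-statistic, accepted at p < 0.01 with both flanks >= 10 probes. The max-t
selection inflates the per-split false-positive rate slightly beyond the
nominal alpha, which occasionally yields an extra low-amplitude segment on
pure noise; gain/loss calls at |log2| >= 0.5 are unaffected. Segment values
equal the mean of their probes exactly. No GC correction is applied; a sum
of channels without further normalisation is used as the combined signal.
Output follows SEG conventions (1-based coordinates).

## Epigenetic age

A clock is a linear model ea = intercept + sum_i w_i * beta_i, with
coefficients read from CSV so any published set (e.g. a PhenoAge-style
table) can be dropped in; coefficients are data, not code, and tests use
synthetic clocks. Missing clock probes are imputed by cohort mean beta (or
rejected under the strict policy); samples covering less than 80% of the
clock raise an error naming the missing probes. Group statistics: a 2x2
contingency of EA > CA (strict inequality; EA = CA counts as "not larger")
tested by Pearson chi-square without continuity correction — the variant
that reproduces p = 0.021 from a 9/16-vs-3/17 table — and a two-sided
Mann-Whitney U on EA - CA (exact for min(n) <= 8 without ties, otherwise
the tie-corrected normal approximation).

## Cohort statistics

Methylation extremes are counted per cohort over all sample x probe
observations (beta > 0.8 hypermethylated, beta < 0.1 hypomethylated;
a per-probe-mean mode exists as a robustness check) and contrasted as
(count_FP/count_SD - 1) x 100. The multivariate analysis uses Bayesian
logistic regression as a penalized MAP fit with independent Cauchy priors
(scale 2.5 on standardized covariates, 10 on the intercept), which keeps
estimates finite under the complete separation that 33-sample cohorts
produce by chance; Wald z and two-sided p come from the observed information
at the MAP, and the fit converges to the maximum-likelihood solution as the
prior scale grows. Incomplete clinical covariates are fitted one per model
on complete cases, without imputation.

## Synthetic cohorts

The generator emulates the study design: two groups at the same disease
stage (defaults 16 FP / 17 SD, matching a 22-train/11-test split), plate
batches, ~10k probes on 22 autosomes with 5 kb spacing except planted DMR
clusters at configurable sub-maxGap spacing.

* Baseline probe means come from a three-state beta mixture (42/14/44%
  unmethylated/hemimethylated/methylated); type II probe means are shrunk
  toward 0.5 by a factor 0.75, reproducing the compressed type II range.
* Within-probe noise is logit-normal: N(0, 0.25) on the M scale, the level
  of routine FFPE array replicates. Because the noise is Gaussian on exactly
  the scale the linear models assume, moderated-t p-values are well
  calibrated — a deliberate property: calibration failures downstream then
  indicate implementation bugs, not model mismatch.
* Group effects are added on the beta scale at planted DMP/DMR probes and
  clipped to [0, 1]; plate effects are logit-scale shifts; copy-number
  segments multiply both intensity channels by 2^shift; clock probes are
  linear in chronological age with 2-year noise on the recovered age;
  detection failures inflate detection p for a random probe subset.
* The planted classifier signature is a hyper/hypomethylated CpG pair
  (delta 0.28) sharing a latent per-sample factor; the first two samples of
  each group carry +/- delta latent excursions that place them at the
  opposite class centroid on every single panel probe. No single probe (nor
  a planted probe paired with noise) can then separate the groups, while the
  pair difference cancels the latent factor exactly — the minimal separating
  panel has size 2 by construction, robustly across seeds.

What the generator does not emulate: cell-composition gradients, probe
cross-hybridisation, SNP-affected probes, sex chromosomes, spatially
correlated array artefacts, or raw IDAT-level dye effects. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not performance on real bone-marrow data.

## Numerical choices and degenerate inputs

Beta clamp 1e-3 before logit; EM tolerance 1e-5; ridge 1e-6 x trace/k on
near-singular scatter and covariance matrices; variance floor 1e-12 with a
flag; BH ties and DMP ordering are stable (p, then |t|, then probe id);
delta = 0 counts as "EA not larger than CA"; empty p-vector returns empty
q-vector; single-batch ComBat returns its input; chi-square with a zero
margin, empty cohorts, missing panel probes and k > m subset requests raise
typed validation errors.

## Problem sizes

Tests and the acceptance script run cohorts of 600-8000 probes and 16-33
samples, 20-250 permutations/repeats per stochastic check — sizes at which
every planted effect is comfortably detectable and a full run takes seconds.
All stages scale linearly in probes (the branch-and-bound search is capped
by its 40-candidate pool) and have been run unchanged at 10k probes.

## Known limitations

The exact branch-and-bound is exponential in the worst case and is therefore
capped at a 40-candidate pool; the DMR permutation p is family-wise and
conservative; Wallenius odds use a single per-term probe-count ratio rather
than per-gene weights; the Cauchy-prior MAP reports observed-information
standard errors, not posterior quantiles; reproducing cohort-specific
published values (specific CpG identities, coefficient tables, evaluable
probe counts) requires the original array data and is out of scope.
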