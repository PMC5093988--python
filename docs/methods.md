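# Methods

This note documents the statistical model behind `ska2sig`, the synthetic
cohorts it is tested on, the numerical conventions, and the design choices
made where the method description left the design open.

## Preprocessing model

Beta values are defined as β = M/(M+U+100), with M and U the methylated
and unmethylated channel intensities; the offset bounds β strictly below 1
and stabilizes low-intensity probes. Channel-wise quantile normalization
maps every sample column of a channel onto the mean of the sorted columns;
ties are resolved by average rank (values at tied ranks receive the linear
interpolation of the reference at the average rank position), which makes
the operation deterministic and idempotent to machine precision.
Cross-reactive probes are removed before analysis using an annotation
flag; probes absent from the annotation are kept by default (configurable).
Raw-probe quality trimming is modeled as an optional missingness mask —
full array preprocessing (IDAT parsing, background and dye-bias
correction, type I/II scale correction, detection P values) is out of
scope; only the two computations above are implemented.

Matrices are probes × samples; genomic positions are 1-based and carry an
assembly tag that is never converted.

## Probe-wise linear models

Both the cortisol EWAS and the brain interaction screen are per-probe OLS
fits sharing one design matrix across probes, computed as a single
multi-response least squares solve; the reported P is the two-sided t test
on the focal coefficient. Complete-case analysis is applied per probe;
constant probes and rank-deficient designs are flagged undefined rather
than dropped, a constant phenotype is a global error. Sex enters as a
single 0/1 indicator; when cell proportions are used as covariates, all
but one cell-type column should be supplied to avoid collinearity with the
intercept.

The interaction screen's default orientation treats probe methylation as
the response with suicide status, SKA2 CpG methylation and their product
as predictors (plus age, sex, genotype). The source description admits a
second reading — a three-way interplay of probe methylation with SKA2
methylation and genotype — so the alternative orientation
`probe ~ ska2m + genotype + ska2m·genotype + age + sex` is available by a
config switch; neither is treated as authoritative. Samples with genotype
0 carry no rs7208505 CpG, have undefined SKA2 methylation, and drop out of
any model containing that term.

## Discovery algorithm conventions

* Candidate selection is strict (P < cutoff, default 0.005), ordered by
  probe ID for determinism.
* The AUC filter refits the full prediction model per candidate by
  default; ranking by the raw probe beta's AUC is available
  (`probe_alone=True`). The retention threshold is the empirical 75th
  percentile of candidate AUCs using type-6 (Weibull, (n+1)p) plotting
  positions, with strict retention (>), so a degenerate all-equal AUC set
  retains nothing. The percentile — not a fixed AUC such as 0.825 — is the
  shipped rule, since any fixed value is cohort-specific.
* PCA centers per probe by the training mean with no scaling; the first
  right singular vector of the centered samples × probes matrix supplies
  the loadings. Eigenvector sign is intrinsically arbitrary, so it is
  fixed once at training: training scores must correlate nonnegatively
  with per-sample mean methylation over the retained probes (tie-break:
  first nonzero loading positive). Projection is x = (β − μ)·v, so
  projecting the training cohort reproduces training scores exactly.
* Missing model probes at projection are an error by default; mean-fill
  (zero contribution) is opt-in, and more than 20% missing is always an
  error.
* Driver probes are retained probes with Spearman P < 0.05 against the
  projected score in *every* cohort of at least 5 samples.

## Prediction model and inference

Logistic regression of the binary outcome on
`ska2m + genotype + ska2m·genotype + term + term·ska2m` (the method's
source never prints its formula; this fixed term set is the documented
default and the state `term` is pluggable: biosignature score, myeloid
fraction, or one probe's beta). Newton fitting is capped at 50 iterations;
perfect separation is caught, flagged, and the fitted probabilities of the
final (L-BFGS) iterate are still returned. AUC is the rank-based
Mann–Whitney statistic, so ties contribute half weight. In-sample AUC
(fit and evaluate on the same cohort) mirrors small-cohort practice in
this literature and is what the Monte Carlo null calibrates against.

The 95% CI is a stratified percentile bootstrap (cases and controls
resampled separately; 2.5/97.5 percentiles; upper capped at 1). The Monte
Carlo null redraws k probes uniformly without replacement (k = size of the
biosignature, default 72), retrains the PCA, refits the model and records
the AUC; the empirical P uses the plus-one estimator
(1 + #{null ≥ observed})/(1 + n_perm), which can never reach 0 and floors
at 1/1001 for 1000 permutations. Degenerate permutation fits are recorded
as AUC 0.5 and counted, never dropped. Probe-set permutation is the
default; outcome-label permutation would answer a different null and is
not conflated with it.

## Cell deconvolution

Reference-based estimation à la Houseman: per sample, weights minimize
‖R·w − β‖² subject to w ≥ 0, solved by NNLS; if the NNLS solution's sum
exceeds 1 + 0.05 the problem is re-solved under the explicit sum-≤-1
constraint (SLSQP from the normalized NNLS start). Weights are reported
raw — not renormalized to sum to 1 — and the residual norm accompanies
every sample. The myeloid-derived fraction is the granulocyte + monocyte
weight. Buccal augmentation appends one column equal to the per-locus mean
of the buccal profiles and restricts the reference to the n most
discriminating shared loci (default 500), ranked by the between-cell-type
variance of the augmented profile row — the numerator of a one-way F over
cell types, which is the only part computable from a mean-profile
reference without replicates.

## Enrichment and associations

Gene-level significance is the minimum P over a gene's probes (no
Šidák-style correction for probe count — a documented simplification);
probes without a gene symbol are excluded, multi-gene probes count for
each gene. The overrepresentation test at tier t uses background
B = intersection of the two gene universes, expected probability
p0 = |T|/|B|, estimate |Q∩T|/|Q|, and an exact one-sided (greater)
binomial P (two-sided behind a flag; trial counts are too small to settle
sidedness from printed tables alone). Default tiers 0.05/0.01/0.001.

Spearman correlations use average-rank ties and the t-approximation P; an
Anderson–Darling normality check (α = 0.05) on both inputs is reported
alongside — non-normal inputs mandate the rank test, normal ones still get
it by default for comparability. The HPA interaction model is OLS of the
cortisol outcome (post-stress-test AUC cortisol, or ln day-2 cortisol
after dexamethasone suppression — nonpositive values are a hard error) on
biosignature + CTQ + biosignature·CTQ plus at most a configured covariate
slot. A published fit of this form reports denominator df implying exactly
4 predictors; the fourth is unstated, so the default model has 3
predictors and the covariate slot (e.g. age) reproduces the 4-predictor
structure when desired.

## Synthetic cohorts: what they emulate and what they do not

The generator plants exactly the structure the analysis assumes:

* **Brain** (default N = 45, 22 cases — the discovery design): planted
  probes follow baseline + a·case + b·ska2m + c·case·ska2m + noise with
  c = 0.15 by default; other probes are noise around a uniform baseline.
  rs7208505 genotype is Hardy–Weinberg (CpG-preserving allele frequency
  0.6), CpG methylation exists only for genotype ≥ 1.
* **Peripheral** (train_blood 120, saliva 80, validation_blood 376 —
  the validation size mirrors the largest real validation cohort; the
  training cohort is enlarged beyond the tiny real training sets because
  a per-probe AUC filter on ~18 samples is dominated by noise): β =
  Σ_k w_k·reference_k + loading·latent + noise, cell weights Dirichlet
  with granulocyte-dominant concentrations, loadings ~ ±N(0.06, 0.015) on
  the 72 biosignature probes (a fixed per-study draw shared by all
  cohorts), Gaussian beta noise sd 0.02 with clipping to [0,1) (clipping
  fraction monitored, < 1% at defaults). The latent factor is constructed
  to correlate −0.6 with the myeloid fraction. Outcomes are logistic in
  the SKA2 fields and the latent factor; cortisol, IL-6 (values below a
  detection limit coded 0), CTQ and perceived stress have linear links to
  the latent factor. The effect sizes have no published scale; these
  defaults were chosen once so that every planted effect is recoverable at
  the stated cohort sizes, and they are all exposed in `SimulationConfig`.

Not emulated: genome-wide methylation covariance beyond the cell-mixture
component, batch/chip effects, type I/II probe chemistry, and logit-scale
(rather than clipped-Gaussian) beta noise. Passing tests therefore show
the pipeline recovers the structure it assumes at realistic noise — not
that real cohorts satisfy those assumptions.

## Problem sizes used by the test suite and acceptance script

Calibration and null checks run at 20,000 probes × n = 200; power and
bias checks at n = 200 with 5,000 probes; the Monte Carlo uniformity check
uses 200 replicates of n_perm = 199 at a reduced scale (250 probes, 60
samples, k = 20 — the calibration property is scale-free); bootstrap
coverage uses 200 cohorts of n = 200 with 1,000 resamples; the end-to-end
study runs at the full default 20,000 probes × 4 cohorts with 200–500
permutations per evaluation. The acceptance script reports every quantity
from a fresh run at the seed it is given.

## Known limitations

* In-sample AUC is optimistic in small cohorts (a leave-one-out mode
  exists but is not the default, matching the practice being modeled).
* The exact binomial overrepresentation test is conservative for discrete
  small-|Q| settings.
* The min-P gene collapse favors genes with many probes.
* The Monte Carlo null inherits the cohort's mixture structure: random
  probe sets partially track cell composition, which is precisely why the
  test is informative about the biosignature's added value, but it makes
  the null AUC distribution cohort-specific.
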