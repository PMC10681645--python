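# Methods

## The statistic

Per subject, every atlas region is described by 47 radiomics features (14
first-order intensity statistics, 8 shape descriptors, 25 GLCM texture
measures).  Features are min-max normalized per feature across the
subject's regions, features with cohort-level |r| > 0.9 to an already
retained feature are dropped (one shared mask for the whole cohort), and
the regional radiomics similarity network (R2SN) is the Pearson
correlation between every pair of regions' retained-feature vectors.  The
regional mean connectivity strength (RMCS) of region *i* is the mean of
its edge weights, diagonal excluded:

    RMCS_i = (1 / (N-1)) * sum_{j != i} w_ij

By default the signed edges are averaged; an `absolute` switch averages
magnitudes instead.  The redundancy correlations are pooled across
subjects (regions x subjects observations) because a per-subject mask
would place different subjects' RMCS on different feature sets and make
group contrasts meaningless.

Group analysis residualizes RMCS on [intercept, age, sex] by OLS over all
subjects pooled, then computes a one-way ANOVA across NC/MCI/AD and
two-sided pooled-variance t contrasts per region (Welch available by
config), Bonferroni-corrected over the region count (strict p < alpha/N).
Robustness is assessed by repeatedly (default 1000x) drawing 80% of each
group without replacement, redrawing (cap 100) until age is balanced
(ANOVA p > .05), and correlating the subsample's -log10 p ANOVA map with
the full-sample map; the report gives the fraction of iterations with
r above 0.5.  Clinical correlations (MMSE, ADAS-cog11/13, AVLT-Im,
Memory, Executive) are within-group Pearson r on the residualized RMCS,
intentionally uncorrected, with pairwise deletion of missing scores.

## PLS and spatial nulls

The AD-vs-NC t-map (predictor) is related to the regions-by-genes
expression matrix (response) by partial least squares.  With a univariate
predictor the first component is closed-form: after z-scoring the map and
every gene column across the retained regions, the response weight vector
is the per-gene covariance with the map normalized to unit length, the
PLS1 regional score is the projection of the standardized expression onto
it, and the explained variance is the Frobenius fraction of the rank-1
reconstruction.  This identity (weights proportional to gene-map
covariances) is asserted in the tests and cross-checked against
scikit-learn's NIPALS implementation.  Genes are ranked by |weight| with
alphabetical tie-breaking; the top-500 list (top-1000 exported) feeds the
cell-type restriction and external enrichment tools.

Map-map correlations are tested against variogram-matched surrogates:
permute the map, smooth the permutation over each region's k = 0.7*N
nearest neighbours with an exponential distance-decay kernel at several
candidate length scales (distance quantiles 0.02-0.7), and least-squares
fit non-negative factors (a, b) so the variogram of sqrt(a)*smoothed +
sqrt(b)*independent-permutation matches the source variogram over 25
distance bins spanning up to the 70th percentile of pairwise distance;
the best-fitting scale wins.  The fit is weighted by sqrt(pair count) /
source magnitude so sparse or near-zero bins neither dominate nor get
sacrificed.  The two-sided p-value uses the add-one permutation
estimator, p = (1 + #{|r_surr| >= |r_obs|}) / (1 + B).  One ensemble is
built on the t-map and shared by the PLS score, the 28 AD-risk gene
correlations and the seven cell-class associations, so all spatial tests
face the same null.  Desk default B = 1000 (config up to 10,000).

Cell-class signatures average the z-scored profiles of each class's genes
(restricted to the expression pool and, by default, to the top-500 PLS
genes) and z-score the class column across regions, giving the
regions-by-7 matrix whose columns are correlated with the t-map.

## Synthetic cohort

The generator supplies every input with the statistical structure the
analysis assumes, under one seeded RNG per operation.

Region archetypes are smooth: latent positions are a 12-dimensional
Gaussian random field over the region centroids with an exponential
kernel of length 180 mm, mapped to unit-variance feature profiles G.  A
subject's region row is

    x[s,i,:] = mu + s_si * G_i + sqrt(1 - s_si^2) * noise,
    s_si^2   = logistic(2 * (0.7 + 1.6*(eta_si - d_s*[i planted]) - 0.01*(age_s - 73.5)))

so each row has constant total variance and `s` is the fraction aligned
with the archetype — a latent "morphological integrity".  Disease
(d_s = 0, d/2, d for NC/MCI/AD in planted regions) replaces archetype
signal with idiosyncratic morphology, decorrelating the region from its
neighbours and lowering its RMCS; this is the disconnection signature the
statistic targets.  The constant-variance form matters: the pipeline's
min-max normalization cancels any additive component shared across
regions, so purely additive latent shifts do not reach the network, and
pure amplitude scaling interacts pathologically with the normalization.
The internal constants (latent dimension 12, archetype length 180 mm,
baseline integrity logit 0.7, subject latent sd 1.6) were fixed once so
that a unit latent effect at 100 subjects/group is recoverable by the
Bonferroni-corrected t-map with high sensitivity while null regions stay
at the nominal type-I level, and so single-subject edge distributions
(mean ~0.2, mostly positive, heavier near anatomically close pairs) look
like real radiomics similarity networks.  Ages are Normal(73.5, 6-8 y)
with a +1.4 y AD shift; clinical scores are linear in each subject's
realized latent burden with intercepts/slopes/noise set to reproduce the
NC-to-AD spans typical of memory-clinic cohorts (MMSE 29 -> 23, ADAS-cog11
7 -> 20, ...), plus 0.2% missingness.

Expression maps are Gaussian random fields over centroid distance
(exponential kernel, default 40 mm); a seeded 20% of genes additionally
load on the standardized planted-effect map with correlation 0.5 and
random sign; a seeded subset of regions (default 10 of 246) is removed
entirely and recorded in the ledger.  Gene names embed the 28-symbol
AD-risk compilation so the risk-gene analysis is exercised end to end.
Cell-class gene sets are random draws (overlap permitted, as in real
compilations).

What the generator does **not** emulate: real MRI contrast and anatomy,
registration or bias-field artifacts, the empirical covariance of real
radiomics features (collinearity here is mild, so the redundancy filter
usually keeps all 47 synthetic features), hub structure of real
connectomes, donor-specific AHBA noise, or biologically meaningful gene
sets.  Passing tests therefore validate the statistical machinery — not
that any particular biological conclusion would replicate.

## Numerical choices and degenerate inputs

- Pearson edges are clipped to [-1, 1] and symmetrized exactly; a region
  with zero feature variance gets a zero row/column and a flag.
- Min-max normalization maps constant feature columns to 0; flagged
  (sub-2-voxel) regions are excluded from the min/max extremes.
- The redundancy scan is greedy in catalog order with first-retained-wins
  tie-breaking; at threshold 1.0 exact duplicates (|r| within 1e-12 of 1)
  still drop.
- t-tests with zero variance in both groups and equal means return t = 0,
  p = 1; ANOVA p-values are clipped at 1e-300 before -log10.
- GLCM quantization uses 32 fixed-count bins over the region's own range
  (hence invariance to positive affine intensity maps); 13 unique
  distance-1 offsets, symmetric accumulation, normalize-then-average.
  Degenerate co-occurrence matrices return 0 for correlation-type
  features.
- Surface area is the exposed-voxel-face estimate; maximum 3D diameter is
  computed on the axis-extreme shell when a region exceeds 512 voxels.
- Surrogate p-values use the add-one estimator and are therefore bounded
  below by 1/(B+1).

## Problem sizes

The default configuration (30 subjects/group, 60 regions, 800 genes, 200
surrogates, 200 bootstrap iterations) runs the whole pipeline in about a
second on one CPU.  The acceptance script uses the full study design —
246 regions, 605/766/283 subjects, 15,633 genes on 236 expression
regions, 1000 surrogates and 1000 bootstrap iterations — and completes in
about a minute.  The statistical test suites use 246-region cohorts at
100 subjects/group (parameter recovery), 200-replicate calibrations at
80-100 regions (surrogate nulls), and 12-region micro-cohorts for the
type-I sweep.

## Known limitations

- Whether the original analysis averaged signed or rectified edges is
  not derivable from the statistic's definition alone; signed is the
  default and a config switch covers the alternative.
- The exact 47-feature catalog of the reference implementation is not
  public in the main text; the default catalog preserves the family
  structure (14 intensity / 8 shape / 25 GLCM) and is config-driven so an
  exact list can be substituted without code changes.
- "AD-related genes" for the cell-type restriction is ambiguous; the
  default (top-500 PLS genes) is switchable to the 28-gene risk list or
  no restriction.
- PLS explained variance is reported as the rank-1 reconstruction
  fraction of the standardized expression; other conventions (regression
  R^2) would differ.
- The surrogate ensemble is built on the t-map, not per gene map;
  building per-gene ensembles is supported by the API but quadratically
  more expensive.
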