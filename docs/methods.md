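# Methods

## The analysis

`stagetx` implements a stage-wise imaging-transcriptomics pipeline. The
inputs are, per illness stage, an unthresholded case-control z-map on a
masked voxel grid, plus a table of brain tissue samples with mm (MNI)
coordinates and a genes x samples matrix of normalized expression values.
The pipeline:

1. **Sphere extraction.** For each sample, the mean z over in-mask voxels
   whose centers lie within 6 mm (Euclidean, boundary-inclusive) of the
   sample coordinate. Samples whose sphere contains no in-mask voxel are
   excluded, not zero-filled. No interpolation is used anywhere, so an
   exhaustive per-voxel distance check reproduces the extraction exactly.
2. **Stage-wise association.** Per gene, Pearson r between its expression
   profile and the per-sample z values; two-sided p from the exact
   t transform with n-2 degrees of freedom; Benjamini-Hochberg FDR within
   each stage; significance at q < 0.05 (strict). Genes with zero
   expression variance are flagged undefined and excluded from FDR.
3. **Cross-stage intersection.** The genes significant in all three
   stages.
4. **Overlap permutation test.** Per iteration, one independent
   variogram-matched surrogate of each stage's sample-value vector; the
   full correlate -> FDR -> threshold -> intersect pipeline re-runs on the
   surrogates and the overlap count is recorded. The empirical p is the
   raw proportion of null counts at or above the observed count (an
   optional `(1+k)/(1+n)` correction exists but is off by default).
   Expression is held fixed under the null: only the phenotype maps are
   randomized.
5. **Gene-category enrichment (GCEA).** Gene score = mean of |r| over the
   three stages (genes defined in all three only); category score = mean
   gene score over members present in the analysis; null distribution from
   an ensemble of randomized phenotypes (one surrogate per stage per
   draw), upper tail only; BH-FDR across categories. Category membership
   is read from GMT files and size-filtered (default 5-500) after
   restriction to the analyzed genes.

"Average of the sum of absolute correlations across stages" is read as
(|r_1|+|r_2|+|r_3|)/3, i.e. the per-stage average; only large scores can
indicate enrichment because the score is a magnitude, hence the one-sided
test.

## Surrogates

The spatial null must preserve spatial autocorrelation while scrambling
topography, otherwise the overlap and enrichment tests are anti-
conservative. Surrogates are generated at the sample-coordinate level (the
vectors that enter the correlations), not at the voxel level; this is an
approximation to voxel-map surrogates but makes a 1000-iteration ensemble
cheap, and downstream inference consumes only sample values.

The generator is a variogram-matching smoothed-permutation algorithm:

1. Standardize the input vector; compute its Matheron empirical variogram
   on equal-width distance bins (default 15) up to half the maximum
   pairwise distance (long-range bins are noisy).
2. Randomly permute the values.
3. Smooth the permutation with a Gaussian kernel over each point's nearest
   neighbors (default 50, the point itself included, so the zero-bandwidth
   limit is a pure permutation). Candidate bandwidths default to a
   geometric grid spanning 0.5x-4x the median nearest-neighbor distance in
   5 steps; that distance plays the role of the sampling resolution.
4. For each bandwidth, least-squares fit `target ~ beta * smoothed-variogram
   + alpha`, with the offset constrained to alpha >= 0 - alpha is the
   variance of the white-noise (nugget) component added next, so a
   negative value is meaningless and, if carried through an absolute
   value, injects a spurious nugget that flattens the realized variogram.
5. Pick the bandwidth with the smallest residual; the surrogate is
   `sqrt(beta) * smoothed + sqrt(alpha) * white noise`, rescaled to the
   original mean and sd exactly. Optional rank-remapping onto the original
   value multiset (off by default; Pearson-based downstream analyses are
   insensitive to the marginal).

Degenerate inputs: a constant vector passes through unchanged; if all
pairwise distances are equal (no geometry to preserve) the generator falls
back to a pure permutation with a logged warning.

On the default synthetic geometry (300 samples, ~7 mm median spacing,
6 mm field smoothing) the realized surrogate variogram correlates >= 0.9
with the original's in ~99% of draws while the surrogate-to-original value
correlation stays below 0.3 - autocorrelation kept, topography randomized.
A plain permutation fails the same variogram check, which is exactly the
gap the surrogate null closes.

## Synthetic data generator

The generator emulates the study's data layout with a known ground truth:

- **Stage maps.** Gaussian random fields: white noise convolved with an
  isotropic Gaussian kernel (sigma = `smoothing_length`, default 6 mm) and
  standardized over the mask. The filter uses periodic boundaries so the
  field is stationary and its marginals exactly Gaussian; edge-replicating
  boundary modes inflate corner variance and produce heavy-tailed maps.
- **Grid.** Default 32x32x32 voxels at 3 mm (a ~96 mm box at standard MNI
  resolution). The box must be large relative to the smoothing length:
  with too few spatial degrees of freedom the three stage fields acquire
  large empirical cross-correlations and the planted-coupling geometry
  (below) degrades.
- **Samples.** Uniform draws without replacement from in-mask voxel
  centers (optional sub-voxel jitter, off by default so sphere extraction
  has an exact oracle).
- **Expression.** Planted gene rows are
  `sign * sqrt(coupling) * target + sqrt(1-coupling) * noise` with
  `noise ~ N(0, noise_sd^2)` and `sign = +/-1` with equal probability;
  null rows are pure noise. Stage-specific genes target their stage's
  standardized sample-value vector. Shared genes target the standardized
  mean of the three stage vectors: a single expression vector cannot
  correlate at full strength with three independent fields, so with
  near-orthogonal maps a shared gene's per-stage correlation is about
  `sqrt(coupling/3)` (~0.41 at the default coupling 0.5). Every row is
  finally squashed to [0, 1] by a scaled robust sigmoid
  (`1 / (1 + exp(-(x - median) / IQR))`, then min-max rescaled). The raw
  IQR as sigmoid scale keeps the transform nearly linear over the bulk of
  a Gaussian-like row (correlations attenuate by well under 0.01), so
  planted correlations survive normalization.

What the generator does **not** emulate: donor structure, probe selection
or any other microarray preprocessing step, hemisphere asymmetries,
spatially autocorrelated *expression* noise, and gene-gene coexpression
among null genes. Passing tests therefore demonstrate correctness of the
pipeline's statistics under a clean spatial-coupling model, not robustness
to every artifact of real atlas data.

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| sphere radius | 6 | mm | the extraction radius the method prescribes |
| alpha | 0.05 | - | FDR level for stage sets and enrichment |
| n_iter / n_null | 1000 | draws | permutation/ensemble sizes of the method |
| smoothing_length | 6 | mm | z-map spatial correlation scale |
| grid / voxel | 32^3 / 3 | voxels / mm | brain-scale box, standard resolution |
| n_samples | 300 | - | desk-scale analogue of ~3000 atlas samples |
| n_genes | 500 | - | desk-scale analogue of a ~1600-gene panel |
| coupling | 0.5 | - | variance fraction of planted genes |
| variogram bins | 15 | - | estimator stability at ~45k pairs |
| bandwidths | geomspace(0.5, 4, 5) x median NN dist | mm | covers the scales where the variogram rises |
| n_neighbors | 50 | - | smoothing support per point |
| category size filter | 5-500 | genes | standard enrichment practice |

## Problem sizes used in the test suite

Simulation-based checks run at deliberately desk-scale sizes chosen as the
package's study conditions: null-calibration checks at 16^3 voxels, 150
samples, 400 genes (200 replicates); power and recovery checks at the
default grid with 200 samples, 400 genes, 20 shared + 3x10 stage-specific
planted genes (50 replicates); surrogate fidelity at the default geometry
with 100 draws; permutation tests at 99 iterations inside replicated runs
and 1000 iterations in single-run demonstrations.

## Numerical choices

- Sphere membership uses voxel centers and an inclusive boundary, with a
  relative 1e-12 tolerance so exact-boundary voxels are kept under float
  round-off.
- Pearson r is computed by standardized matrix products and clipped to
  [-1, 1]; p-values use the survival function of the t distribution.
- BH-FDR delegates to `statsmodels.multipletests(method="fdr_bh")` and is
  validated against an independent O(m^2) step-up implementation in the
  tests.
- Variogram bins are equal-width from zero; zero-distance pairs fall in
  the first bin; pairs at exactly the last edge are kept; empty bins carry
  NaN and are excluded from fitting.
- Determinism: every stochastic component takes an explicit seed; the
  pipeline fans a single master seed out to per-stage child seeds via a
  fixed `SeedSequence` spawn order, and identical configurations reproduce
  outputs byte-for-byte (NIfTI gzip included; the manifest timestamp is the
  only exception).

## Known limitations

- **The overlap statistic is discrete.** On fully null data (no gene-map
  coupling, iid expression noise) the per-stage FDR is exactly valid, a
  gene must survive it in three independent stages to enter the
  intersection, and the observed count is almost surely zero - so the
  permutation p has an atom at 1 and the test rejects far *less* often
  than 5% on null data. It is valid but conservative; its p-value is not
  uniform under this null and cannot be. Power against genuinely shared
  signal is excellent (planted couplings are detected at p_perm ~ 0).
- **Category nulls are category-specific.** The expected |r| of a gene
  against a spatially smooth surrogate depends on how much of that gene's
  profile lies along smooth spatial directions, so equal-size categories
  have slightly different null distributions on the same data. Inference
  therefore always compares a category to its own null ensemble; null
  distributions must not be pooled or swapped across categories.
- Surrogates are sample-level, not voxel-level; variogram preservation is
  enforced only up to half the maximum pairwise distance and at the
  resolution of the sampling.
- Sphere extraction with very sparse masks can exclude samples; excluded
  samples are dropped from all stages jointly by the pipeline runner so
  every stage correlates over the same sample set.
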