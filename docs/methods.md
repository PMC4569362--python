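# Methods

This note records the statistical procedures the package implements, the
modelling choices behind the synthetic data generator, and the numerical
conventions that matter for reproducing results.

## ROC analysis

Both AUC variants reduce to the Mann–Whitney U statistic computed with
midranks:

    AUC = (R_pos − n_pos(n_pos+1)/2) / (n_pos · n_neg)

where `R_pos` is the rank sum of the positive-sample map values in the
pooled ranking.  This equals the trapezoidal area under the empirical ROC
curve and handles ties exactly (a constant map scores exactly 0.5).  The
unit tests verify equality with an exhaustive pairwise-comparison oracle to
1e-12 and cross-check against an independent ROC implementation.

*Standard AUC* draws `ceil(r · n_pos)` negatives uniformly, seeded, without
replacement from pixels not covered by a positive (default `r = 1`;
dataset-level benchmarking uses `r = 5` to reduce sampling noise).
Published descriptions of standard ROC scoring differ in their negative-set
construction, so the ratio is explicit and configurable.

*Shuffled AUC* takes its negatives from the same-task selection points of
all *other* images in the dataset, excluding any location that is a
positive on the scored image, capped at `10 · n_pos` by seeded subsampling.
Because positives and negatives then share the dataset's spatial
distribution, a map that depends only on position (e.g. a central Gaussian)
scores 0.5 in expectation.  One geometric caveat: the positive-pixel
exclusion itself removes high-density locations from the pool, which biases
the score upward when the point sets are dense relative to the grid.  The
neutrality check therefore runs on a 512×512 grid, where 2000 central
points occupy only a few percent of the central region and the exclusion
effect is negligible.

## Fixation density and blur levels

Point sets become continuous densities by accumulating per-pixel counts and
convolving with an isotropic Gaussian of

    σ = blur_level × sigma_per_level × max(height, width)

with `sigma_per_level = 0.01`, i.e. blur level k ≙ k% of the longer image
side, then renormalizing to unit mass (mass blurred past the border is
folded back by the renormalization).  Integer blur levels 1–7 are a
conventional sweep in saliency evaluation; the mapping from level to σ is
this package's explicit convention, since no standard one exists.  Level 0
means the raw impulse map.

## Inter-observer congruency

IOC of an image is the mean over observers of the standard AUC of the
held-out observer's points against the blurred density of all other
observers' points (default blur level 3, negative ratio 5).  It serves as
an empirical performance ceiling.  The inner metric and its parameters are
configurable; with uniform random observers IOC is 0.5 in expectation, with
identical observers it saturates at 1.  Note the uncertainty of the
estimate is dominated by the number of points per observer, not by the
negative sample size.

## Spatial bias and its removal

The spatial-bias profile of an algorithm over N maps is
`M_bias = (1/N) Σ_i (M_i − μ_i)/σ_i − μ_m`, re-centered to zero mean.  For
content-free (i.i.d. noise) ensembles its per-pixel values are ~N(0, 1/N),
so the *maximum* over P pixels concentrates near `sqrt(2 ln P / N)` — about
0.26 for N = 200 on a 32×32 grid, falling below 0.1 only around N ≈ 2000.
Tests assert these extreme-value-consistent bounds.

Rank-order removal replaces, at every pixel, the N cross-map values by
ascending rank / N.  Exact ties receive midranks (the mean of the tied rank
positions), which keeps the per-pixel sum identity `Σ_i M_i(x,y) = (N+1)/2`
in expectation and makes the transform order-independent; for tie-free
input the identity is exact.  The transform is invariant under any strictly
increasing transform applied to all maps.

Whitening-based removal first whitens each map (mean 0, SD 1), then
whitens the N values at each pixel across maps.  *Population* (divide-by-N)
standard deviations are used throughout: this keeps the N = 2 case well
defined (any unequal pair maps to −1, +1) and reads "standard deviation of
M_i" as a descriptive statistic.  After the per-pixel stage,
`Σ_i M_i(x,y) = 0` and the cross-map variance is 1 at every pixel.  The
per-pixel stage is idempotent; the composed two-stage operation is not,
because the per-pixel stage deliberately destroys the per-map statistics
the first stage imposed — the composed output is, however, a fixed point of
the per-pixel stage.  Degenerate inputs (a constant map, or a pixel
constant across all maps) raise errors naming the offender rather than
being silently zeroed.

The center-bias ratio curve reports, for 20 evenly spaced radii up to half
the image diagonal, the fraction of points within that distance of the
image center.

## Explicit-judgment prediction

Per-pixel features are: the value of each algorithm's saliency map at the
pixel, optionally the free-viewing fixation density (blur level 3), and
optionally `(x/width, y/height)`.  Positives are all explicit-judgment
locations of an image; negatives are 100 uniform seeded draws per image
from non-positive pixels (balanced classes; the exclusion radius around
positives defaults to 0 and is configurable).  Images are split half/half
into train and test (an odd count favours training), and evaluation
structurally refuses any train/test image overlap.

The regressor is an ensemble of bagged decision trees (random forest): 15
trees by default, bootstrap resampling per tree, ⌈√d⌉ features per split,
unlimited depth, prediction = mean over trees, fully seeded.  Predicted
maps are the per-pixel model output clamped to [0, 1], Gaussian-blurred at
blur level 4 (the level at which prediction performance peaks in this
configuration), and min-max rescaled.  Center-bias removal is *not* applied
in this pipeline, since spatial position is itself a feature in most
configurations.

Two null/ablation controls accompany the headline comparison: training on
permuted labels must leave held-out row-level AUC at chance (its null width
is governed by chance label–feature association in the training draw,
≈ 1/√n_train, not by evaluation noise), and widening the ensemble from 1 to
50 trees must not reduce held-out AUC.

## Judgment simulation

To convert a predicted judgment map into discrete surrogate data, the map
is min-max normalized, pixels below a threshold are zeroed, and 100
locations are drawn with replacement with probability proportional to the
remaining values (duplicates kept as multiplicity, matching the fact that
independent human observers can pick the same pixel).  A sweep of the
threshold (0.1 / 0.3 / 0.5 / 0.7 over six scenario seeds) shows surrogate
ranking fidelity — the correlation between per-algorithm AUCs on simulated
vs true judgments — rising monotonically from ≈ 0.74–0.87 at 0.1 to
≈ 0.98–1.0 at 0.7: observers asked for the *most salient* location
concentrate on peaks, so admitting low-value pixels dilutes the surrogate
data with noise.  The default threshold is 0.5, which achieves robust
fidelity while still dispersing samples over multiple peaks; it is
configurable, and sampling without thresholding (threshold 0) is available
for comparison.

Surrogate benchmarking scores every algorithm against true and simulated
judgment points and reports the Pearson correlation of the two score
vectors (Spearman optional).  The experiment uses a 12-model synthetic
roster (four fidelity levels × unbiased / central / peripheral bias) —
about the number of models a benchmarking study compares, and wide enough
in both bias directions for a stable correlation; a 6-point correlation is
too volatile to be meaningful.

## Synthetic data generator

The generator emulates the *structure* of multi-task selection datasets:

* **Scenes**: 3 Gaussian blobs (σ between 5% and 9% of the image side,
  weights 0.5–1) placed with a border margin on a 64×64 grid; the
  normalized mixture is the latent salience.  64×64 keeps exhaustive
  oracles and full-grid prediction cheap.
* **Observers**: each point is drawn from
  `(1 − w)·latent + w·N(center, (0.15·side)²)`, with task-specific central
  weights w — free viewing 0.5, saliency viewing 0.3, object search 0.2,
  explicit judgment 0.05 — encoding the qualitative ordering that free
  viewing is most center-biased and manual judgment least.  Gaussian jitter
  (SD 1 px) and rounding model selection noise.  Gaze tasks use 10
  observers × 10 fixations per image; explicit judgment uses 100 observers
  × 1 selection, mirroring the structure of real judgment pools (many
  participants, one pick each).
* **Algorithms**: map = peak-normalized latent + i.i.d. Gaussian noise
  (fidelity) + optional zero-mean central-Gaussian bias profile (σ = 20% of
  the side), min-max rescaled.  The default roster spans noise SD 0.15–0.7
  and bias amplitudes 0–1.
* **Masks**: level sets of the latent salience (default 50% of peak).

What the generator does *not* emulate — saccade dynamics, fixation
durations, inter-fixation dependencies, photographic composition,
semantics — bounds what passing tests show: they validate the evaluation
machinery and its bias arithmetic, not claims about real human data.

One deliberately realistic consequence of placing blobs with a border
margin is that content is itself mildly center-distributed (as in real
photographs), so an injected central bias can help even on judgment data;
the ranking-fairness and surrogate experiments account for this.

## Numerical conventions

* Coordinates are 0-based, `x` = column, `y` = row; grids are indexed
  `(row, col)`.
* All randomness flows through `numpy` SeedSequence spawning; identical
  seeds give byte-identical CSV/PNG/JSON outputs across runs and processes
  (string keys are hashed with CRC32, not Python's salted `hash`).
* Maps read from PNG are scaled by the bit-depth maximum; 16-bit round
  trips are exact to 1/65535.
* Precision of an empty binarized set is defined as 1 (avoids 0/0 at the
  top threshold); F is 0 where P + R = 0.
* Rank-transform sum identities hold to the representation error of the
  rationals k/N (~1e-14); whitening identities to 1e-9.

## Known limitations

* Shuffled AUC on small grids with dense point sets is biased upward by the
  positive-pixel exclusion (see above); prefer larger grids or sparser
  pools when that matters.
* IOC compares observers against a *blurred* density, so its value depends
  on the blur level; report it alongside the level used.
* The predictor rasterizes features for every pixel at prediction time;
  for very large images a stride or tiling would be needed.
* The simulator draws i.i.d. points; it does not model per-observer
  individual differences or any ordering of selections.
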