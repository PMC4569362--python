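# saliencybench

Bias-aware benchmarking of visual-saliency maps against human selection
data — eye-tracking fixations from free viewing, object search and saliency
viewing, and manually selected "most salient" locations (explicit
judgments).

## The problem

Saliency algorithms are usually scored by how well their output map `M`
separates fixated from non-fixated pixels, summarized as the area under the
ROC curve.  Two well-known biases corrupt this comparison:

* **data bias** — human fixations cluster near the image center regardless
  of content, so any map with central mass looks good;
* **model bias** — algorithms themselves emphasize some regions (usually
  the center, occasionally the periphery) through their computational
  structure alone, so different algorithms are graded on different curves.

This package implements the evaluation machinery needed to measure and
neutralize both:

* **Standard AUC** — negatives sampled uniformly from non-selected pixels;
  **shuffled AUC** — negatives sampled from points selected on *other*
  images, which cancels spatial bias shared by the data.  Both are computed
  as the Mann–Whitney U statistic with midranks (exactly the trapezoidal
  ROC area, exact under ties).
* **Spatial-bias profiles** `M_bias = mean_i[(M_i − μ_i)/σ_i] − μ_m` over an
  algorithm's maps, and the center-bias ratio curve of a point set.
* **Center-bias removal** from a map ensemble, by per-pixel rank transform
  (values become `rank/N`, uniform at every pixel; cross-map pixel sums are
  `(N+1)/2`) or two-stage whitening (per map, then per pixel; cross-map
  sums 0, variance 1).
* **Inter-observer congruency (IOC)** — leave-one-observer-out AUC of each
  observer's points against the Gaussian-blurred density of the others'; an
  empirical ceiling on algorithm performance.
* **Explicit-judgment prediction** — a bagged regression-tree ensemble
  (random forest) over per-pixel features: each algorithm's map value,
  blurred fixation density, and normalized coordinates.
* **Judgment simulation** — sampling discrete surrogate judgment points
  from a predicted judgment map (threshold, renormalize, draw with
  probability ∝ value), so algorithms can be ranked on the explicit-judgment
  task when only eye-tracking data exists.
* **Segmentation scoring** — precision/recall/F-measure
  (`F = P·R / (0.5·(P+R))`) of binarized maps against object masks.
* A **synthetic-data generator** emulating the structure of multi-task
  selection datasets (latent salient blobs; task-dependent central bias in
  observers; synthetic "algorithms" = latent salience + noise + injected
  spatial bias), so everything is testable without any download.

## Worked example

```python
import saliencybench as sb
from saliencybench import experiments

# Does rank de-biasing reconcile the two ROC metrics?
agree = experiments.debias_agreement(seed=1)
print(round(agree["max_abs_diff"], 4))          # 0.0136

# A center-biased low-fidelity model vs a clean high-fidelity one:
fair = experiments.ranking_fairness(seed=3)
print({k: round(v, 3) for k, v in fair["raw"].items()})
# {'biased_lofi': 0.735, 'clean_hifi': 0.7}      <- raw ranking is wrong
print({k: round(v, 3) for k, v in fair["debiased"].items()})
# {'biased_lofi': 0.595, 'clean_hifi': 0.655}    <- fidelity order restored
```

After rank de-biasing, standard and shuffled AUC agree to ~0.01 per
algorithm, and the raw standard-AUC advantage that the center-biased model
enjoyed on center-biased fixation data disappears.  The full simulation
pipeline (`experiments.surrogate_experiment`) trains the judgment
predictor, samples surrogate judgment points, and checks that they rank 12
synthetic algorithms almost exactly as true judgment data does
(correlation ≈ 0.92 at seed 1), far better than raw fixation data
(≈ 0.67).

## Command line

```sh
saliencybench synth     --out data --seed 1          # synthetic dataset
saliencybench benchmark --data data --out bench.csv --seed 1 --debias rank
saliencybench ioc       --data data --out ioc.csv --seed 1
saliencybench biasmap   --data data --algorithm lofi_center --out bias.png
saliencybench debias    --data data --out debiased --mode whiten
saliencybench train     --data data --out model.joblib --seed 1
saliencybench predict   --data data --model model.joblib --out pred
saliencybench simulate  --maps pred --out sim.csv --seed 1
```

Every command writes a manifest JSON echoing its configuration and seed;
rerunning from a manifest reproduces its outputs byte-identically.

## Data formats

Point tables are CSV (`image_id,observer_id,task,x,y,ordinal`; coordinates
0-based, `x` = column, `y` = row).  Maps and masks are single-channel 8- or
16-bit PNG, scaled to [0, 1] on read.  Image dimensions live in a JSON
catalog `{image_id: [width, height]}`.  De-biased (real-valued) maps are
exported as PNG plus a JSON sidecar recording the affine value range.
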