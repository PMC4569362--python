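"""Evaluation statistics for saliency maps and selection data.

Two flavours of ROC analysis are implemented, differing only in where the
negative samples come from:

* **standard AUC** — negatives drawn uniformly from the non-selected pixels
  of the same image.  A map that concentrates mass wherever the *data* is
  spatially biased (e.g. the image center) is rewarded even if the map
  carries no image-specific information.
* **shuffled AUC** — negatives drawn from locations selected on *other*
  images of the dataset.  Positives and negatives then share the dataset's
  spatial bias, so a purely spatial (content-free) map scores 0.5.

Both reduce to the Mann–Whitney U statistic computed with midranks, which
equals the trapezoidal area under the empirical ROC curve with exact tie
handling.

Also here: Gaussian fixation-density maps, leave-one-observer-out
inter-observer congruency (IOC), Pearson correlation, and precision /
recall / F-measure curves for salient-object segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

from .datatypes import PointTable, SaliencyMap, ValidationError, _as_points

#: Default mapping from an integer blur level to a Gaussian sigma:
#: sigma = blur_level * SIGMA_PER_LEVEL * max(height, width).
SIGMA_PER_LEVEL = 0.01


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class DensityMap:
    """A nonnegative grid summing to 1, from Gaussian-blurred point impulses."""

    grid: np.ndarray
    blur_level: int = 0

    def __post_init__(self) -> None:
        if (self.grid < 0).any():
            raise ValidationError("density map has negative entries")
        if not math.isclose(float(self.grid.sum()), 1.0, abs_tol=1e-9):
            raise ValidationError("density map does not sum to 1")

    def as_map(self, image_id: str = "", algorithm_id: str = "density") -> SaliencyMap:
        return SaliencyMap(image_id, self.grid, algorithm_id)


@dataclass
class PrCurve:
    thresholds: np.ndarray   # descending
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray

    @property
    def max_f(self) -> float:
        return float(self.f_measure.max())


def blur_sigma(blur_level: int, shape: tuple[int, int],
               sigma_per_level: float = SIGMA_PER_LEVEL) -> float:
    """Sigma in pixels for an integer blur level on a given grid shape."""
    return blur_level * sigma_per_level * max(shape)


def density_from_points(points, shape: tuple[int, int], blur_level: int = 0,
                        sigma_per_level: float = SIGMA_PER_LEVEL) -> DensityMap:
    """Convert discrete points into a continuous density by Gaussian blurring.

    The per-pixel count map is convolved with an isotropic Gaussian of
    ``sigma = blur_level * sigma_per_level * max(shape)`` and renormalized to
    sum 1.  ``blur_level=0`` returns the normalized impulse map unchanged.
    """
    pts = _as_points(points)
    if len(pts) == 0:
        raise ValidationError("cannot build a density map from an empty point set")
    if blur_level < 0:
        raise ValidationError("blur_level must be >= 0")
    h, w = shape
    if pts[:, 0].min() < 0 or pts[:, 0].max() >= w or pts[:, 1].min() < 0 or pts[:, 1].max() >= h:
        raise ValidationError("point outside grid bounds")
    counts = np.zeros(shape, dtype=float)
    np.add.at(counts, (pts[:, 1], pts[:, 0]), 1.0)
    if blur_level > 0:
        sigma = blur_sigma(blur_level, shape, sigma_per_level)
        counts = gaussian_filter(counts, sigma=sigma, mode="constant")
    total = counts.sum()
    return DensityMap(grid=counts / total, blur_level=blur_level)


def mann_whitney_auc(pos_values: np.ndarray, neg_values: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney U with midranks for ties."""
    pos_values = np.asarray(pos_values, dtype=float)
    neg_values = np.asarray(neg_values, dtype=float)
    n_pos, n_neg = len(pos_values), len(neg_values)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs at least one positive and one negative")
    ranks = rankdata(np.concatenate([pos_values, neg_values]))
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _positive_linear_set(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    return np.unique(pts[:, 1] * w + pts[:, 0])


def standard_auc(smap: SaliencyMap, positives, n_neg_ratio: float = 1.0,
                 seed: int = 0) -> RocResult:
    """ROC area with uniformly sampled negatives.

    Negatives are ``ceil(n_neg_ratio * n_pos)`` pixel locations drawn
    uniformly (seeded, without replacement) from pixels not covered by any
    positive.
    """
    pts = _as_points(positives)
    if len(pts) == 0:
        raise ValidationError("positives must be non-empty")
    pos_values = smap.values_at(pts)
    h, w = smap.shape
    pos_lin = _positive_linear_set(pts, smap.shape)
    n_candidates = h * w - len(pos_lin)
    if n_candidates == 0:
        raise ValidationError("positives cover every pixel; no negatives available")
    n_neg = math.ceil(n_neg_ratio * len(pts))
    if n_neg > n_candidates:
        n_neg = n_candidates
    candidates = np.setdiff1d(np.arange(h * w), pos_lin, assume_unique=False)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_neg, replace=False)
    neg_values = smap.grid.ravel()[chosen]
    return RocResult(mann_whitney_auc(pos_values, neg_values), len(pts), n_neg)


def shuffled_auc(smap: SaliencyMap, positives, negative_pool, seed: int = 0,
                 max_neg_ratio: float = 10.0) -> RocResult:
    """ROC area with negatives drawn from the dataset-wide selection pool.

    ``negative_pool`` holds locations selected on *other* images.  Pool
    entries landing on a positive pixel are excluded; if more than
    ``max_neg_ratio * n_pos`` remain, a seeded subsample caps the cost.
    """
    pts = _as_points(positives)
    pool = _as_points(negative_pool)
    if len(pts) == 0:
        raise ValidationError("positives must be non-empty")
    h, w = smap.shape
    pos_lin = _positive_linear_set(pts, smap.shape)
    pool_lin = pool[:, 1] * w + pool[:, 0]
    keep = ~np.isin(pool_lin, pos_lin)
    pool = pool[keep]
    if len(pool) == 0:
        raise ValidationError("negative pool is empty after excluding positive pixels")
    cap = math.ceil(max_neg_ratio * len(pts))
    if len(pool) > cap:
        rng = np.random.default_rng(seed)
        pool = pool[rng.choice(len(pool), size=cap, replace=False)]
    return RocResult(
        mann_whitney_auc(smap.values_at(pts), smap.values_at(pool)), len(pts), len(pool)
    )


def ioc_image(table: PointTable, image_id: str, task: str, blur_level: int = 3,
              sigma_per_level: float = SIGMA_PER_LEVEL, seed: int = 0,
              shape: tuple[int, int] | None = None,
              n_neg_ratio: float = 5.0) -> float:
    """Leave-one-observer-out inter-observer congruency for one image.

    For each observer, the remaining observers' points are blurred into a
    density map which is scored (standard AUC) against the held-out
    observer's points; the mean over observers is the image's IOC.  IOC acts
    as an empirical ceiling on algorithm performance: no content-driven map
    should predict an observer better than the other observers do.
    """
    observers = table.observers(image_id=image_id, task=task)
    if len(observers) < 2:
        raise ValidationError(
            f"IOC needs >= 2 observers for image {image_id!r} task {task!r}; "
            f"got {len(observers)}"
        )
    if shape is None:
        pts_all = table.points(image_id=image_id, task=task)
        shape = (int(pts_all[:, 1].max()) + 1, int(pts_all[:, 0].max()) + 1)
    aucs = []
    for k, obs in enumerate(observers):
        held_out = table.points(image_id=image_id, task=task, observer_id=obs)
        others = table.points(image_id=image_id, task=task, exclude_observer=obs)
        density = density_from_points(others, shape, blur_level, sigma_per_level)
        res = standard_auc(density.as_map(image_id), held_out,
                           n_neg_ratio=n_neg_ratio,
                           seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31))
        aucs.append(res.auc)
    return float(np.mean(aucs))


def ioc_dataset(table: PointTable, task: str, blur_level: int = 3,
                sigma_per_level: float = SIGMA_PER_LEVEL, seed: int = 0,
                shapes: dict[str, tuple[int, int]] | None = None,
                n_neg_ratio: float = 5.0) -> float:
    """Mean per-image IOC over all images with at least two observers."""
    values = []
    for image_id in table.image_ids(task=task):
        if len(table.observers(image_id=image_id, task=task)) < 2:
            continue
        shape = shapes.get(image_id) if shapes else None
        values.append(ioc_image(table, image_id, task, blur_level,
                                sigma_per_level, seed, shape, n_neg_ratio))
    if not values:
        raise ValidationError(f"no image with >= 2 observers for task {task!r}")
    return float(np.mean(values))


def pearson(xs, ys) -> float:
    """Sample Pearson correlation coefficient; errors on degenerate input."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValidationError("pearson needs two equal-length 1-D arrays")
    if len(xs) < 3:
        raise ValidationError("pearson needs length >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValidationError("pearson undefined for zero-variance input")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def pr_curve(smap: SaliencyMap, mask: np.ndarray, n_thresholds: int = 256) -> PrCurve:
    """Precision–recall–F curve of a binarized map against an object mask.

    The map is thresholded at ``n_thresholds`` evenly spaced levels over
    [0, 1] (descending).  Precision of an empty binarization is defined as 1.
    F is the harmonic mean ``precision * recall / (0.5 * (precision + recall))``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != smap.shape:
        raise ValidationError("mask shape does not match map shape")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValidationError("object mask has no positive pixel")
    thresholds = np.linspace(0.0, 1.0, n_thresholds)[::-1]
    grid = smap.grid
    precision = np.empty(n_thresholds)
    recall = np.empty(n_thresholds)
    for i, t in enumerate(thresholds):
        binarized = grid >= t
        n_bin = int(binarized.sum())
        tp = int((binarized & mask).sum())
        precision[i] = 1.0 if n_bin == 0 else tp / n_bin
        recall[i] = tp / n_mask
    denom = precision + recall
    f = np.where(denom > 0, precision * recall / (0.5 * denom), 0.0)
    return PrCurve(thresholds=thresholds, precision=precision, recall=recall, f_measure=f)
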