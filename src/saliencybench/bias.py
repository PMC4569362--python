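"""Quantifying and removing spatial (center) bias.

Saliency algorithms can emphasize some image regions — typically the
center — regardless of content, simply through their computational
structure.  Such a systematic spatial profile inflates standard-ROC scores
on center-biased fixation data and deflates shuffled-ROC scores, so
different algorithms are effectively graded on different curves.

Two normalizations make the per-pixel value statistics identical across an
algorithm's maps over a dataset, removing that spatial profile entirely:

* **rank transform** — at each pixel, the N values across maps are replaced
  by their ascending rank divided by N (midranks for ties), imposing a
  uniform distribution at every location;
* **whitening** — each map is whitened (mean 0, population SD 1), then the
  N cross-map values at each pixel are whitened again, imposing mean 0 /
  variance 1 at every location.

The spatial-bias *map* and the center-bias *ratio curve* visualize the bias
before removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datatypes import MapEnsemble, ValidationError, _as_points


@dataclass
class BiasProfile:
    """Zero-mean grid of where an algorithm over- or under-emphasizes."""

    grid: np.ndarray
    algorithm_id: str = ""

    def __post_init__(self) -> None:
        if abs(float(self.grid.mean())) > 1e-9:
            raise ValidationError("bias profile must have zero mean")


@dataclass
class BiasRatioCurve:
    """Fraction of points within concentric center circles of growing radius."""

    radii: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ratio) < 0):
            raise ValidationError("bias ratio must be non-decreasing in radius")


def spatial_bias_map(ensemble: MapEnsemble) -> BiasProfile:
    """Average of per-map whitened grids, re-centered to zero mean.

    Each map M_i is whitened to (M_i - mean_i) / sd_i, the N whitened maps
    are averaged, and the grand mean of that average is subtracted.  High
    values mark regions the algorithm emphasizes more than its own average
    behaviour; for content-free maps the profile tends to zero as N grows.
    """
    stack = ensemble.stack().astype(float)
    means = stack.mean(axis=(1, 2), keepdims=True)
    sds = stack.std(axis=(1, 2), keepdims=True)
    flat = np.nonzero(sds.ravel() == 0)[0]
    if len(flat):
        bad = ensemble.maps[flat[0]].image_id
        raise ValidationError(
            f"map for image {bad!r} in ensemble {ensemble.algorithm_id!r} is constant"
        )
    mean_white = ((stack - means) / sds).mean(axis=0)
    return BiasProfile(grid=mean_white - mean_white.mean(),
                       algorithm_id=ensemble.algorithm_id)


def debias_rank(ensemble: MapEnsemble) -> MapEnsemble:
    """Per-pixel rank transform across maps: values become rank/N.

    At each pixel the N values (one per map) are replaced by their ascending
    rank divided by N; exact ties receive the mean of their rank positions
    (midranks).  For tie-free input the per-pixel value set is
    {1/N, 2/N, ..., 1}, so the cross-map sum at every pixel is (N+1)/2 and
    every pixel location carries an identical uniform value distribution.
    """
    stack = ensemble.stack()
    ranks = rankdata(stack, axis=0, method="average")
    return ensemble.with_stack(ranks / ensemble.n)


def debias_whiten(ensemble: MapEnsemble) -> MapEnsemble:
    """Two-stage whitening: per map, then per pixel across maps.

    Population (divide-by-N) standard deviations are used throughout, which
    keeps the N=2 case well defined: any unequal pixel pair whitens to
    (-1, +1).  After this the cross-map sum at every pixel is 0 and the
    cross-map variance is 1.
    """
    stack = ensemble.stack().astype(float)
    means = stack.mean(axis=(1, 2), keepdims=True)
    sds = stack.std(axis=(1, 2), keepdims=True)
    flat = np.nonzero(sds.ravel() == 0)[0]
    if len(flat):
        bad = ensemble.maps[flat[0]].image_id
        raise ValidationError(f"map for image {bad!r} is constant; cannot whiten")
    stage1 = (stack - means) / sds
    return ensemble.with_stack(_pixelwise_whiten(stage1))


def _pixelwise_whiten(stack: np.ndarray) -> np.ndarray:
    """Whiten the N cross-map values at each pixel (mean 0, population SD 1).

    Idempotent: re-applying it leaves an already pixel-whitened stack
    unchanged (up to rounding).
    """
    px_mean = stack.mean(axis=0)
    px_sd = stack.std(axis=0)
    zero = np.argwhere(px_sd == 0)
    if len(zero):
        y, x = (int(v) for v in zero[0])
        raise ValidationError(
            f"pixel (x={x}, y={y}) is constant across all maps; cannot whiten"
        )
    return (stack - px_mean) / px_sd


def center_bias_ratio(points, shape: tuple[int, int], n_radii: int = 20) -> BiasRatioCurve:
    """Fraction of points inside center circles of ``n_radii`` evenly spaced
    radii up to half the image diagonal."""
    pts = _as_points(points)
    if len(pts) == 0:
        raise ValidationError("center_bias_ratio needs a non-empty point set")
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    dist = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    r_max = 0.5 * np.hypot(w, h)
    radii = np.linspace(r_max / n_radii, r_max, n_radii)
    ratio = np.array([(dist <= r).mean() for r in radii])
    return BiasRatioCurve(radii=radii, ratio=ratio)
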