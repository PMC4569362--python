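"""Ensemble prediction of explicit-judgment locations.

Individual saliency algorithms predict manually selected "most salient"
locations to a degree, but an ensemble regressor over their outputs does
better.  Per-pixel features are: the value of each algorithm's saliency map
at that pixel, optionally the free-viewing fixation density (Gaussian
blurred), and optionally the normalized (x, y) coordinates.  Explicit
judgment locations are the positive samples (label 1); uniformly sampled
non-selected pixels are the negatives (label 0).  A bagged ensemble of
regression trees (random forest) is fit to these labels; its per-pixel
output over a full grid, blurred and rescaled, is the predicted
explicit-judgment map.

Center-bias removal is deliberately not applied here: spatial position is
itself a feature in most configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.ensemble import RandomForestRegressor

from .datatypes import PointTable, SaliencyMap, ValidationError
from .metrics import (
    RocResult,
    SIGMA_PER_LEVEL,
    blur_sigma,
    density_from_points,
    shuffled_auc,
    standard_auc,
)
from .benchmark import shuffled_pool


@dataclass
class FeatureSchema:
    """Which per-pixel feature columns the predictor consumes, in order:
    one column per algorithm map, then fixation density, then x/width and
    y/height."""

    algorithm_ids: list[str]
    use_fixation_density: bool = True
    use_xy: bool = True
    blur_level: int = 3
    sigma_per_level: float = SIGMA_PER_LEVEL

    def __post_init__(self) -> None:
        if not self.algorithm_ids and not self.use_fixation_density and not self.use_xy:
            raise ValidationError("feature schema enables no feature source")

    @property
    def n_features(self) -> int:
        return len(self.algorithm_ids) + int(self.use_fixation_density) + 2 * int(self.use_xy)


@dataclass
class TrainingSet:
    features: np.ndarray          # (n_rows, n_features)
    labels: np.ndarray            # 0/1 floats
    provenance: list[tuple[str, int, int]]   # (image_id, x, y) per row
    schema: FeatureSchema
    image_ids: list[str]


@dataclass
class JudgmentPredictor:
    model: RandomForestRegressor
    schema: FeatureSchema
    n_trees: int
    seed: int
    train_image_ids: list[str] = field(default_factory=list)


def split_images(image_ids: list[str], seed: int) -> tuple[list[str], list[str]]:
    """Seeded half/half split; an odd count gives training the extra image."""
    ids = sorted(image_ids)
    if len(ids) < 2:
        raise ValidationError("need at least 2 images to split")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 71]))
    perm = rng.permutation(len(ids))
    n_train = (len(ids) + 1) // 2
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def _pixel_features(image_id: str, pts: np.ndarray,
                    maps: dict[str, dict[str, SaliencyMap]],
                    fixations: PointTable | None, schema: FeatureSchema,
                    shape: tuple[int, int]) -> np.ndarray:
    cols = []
    for aid in schema.algorithm_ids:
        if image_id not in maps.get(aid, {}):
            raise ValidationError(f"algorithm {aid!r} has no map for image {image_id!r}")
        cols.append(maps[aid][image_id].values_at(pts))
    if schema.use_fixation_density:
        if fixations is None:
            raise ValidationError("schema requires fixation density but no fixations given")
        fix_pts = fixations.points(image_id=image_id, task="free_view")
        if len(fix_pts) == 0:
            raise ValidationError(f"no free-viewing fixations for image {image_id!r}")
        dens = density_from_points(fix_pts, shape, schema.blur_level, schema.sigma_per_level)
        cols.append(dens.as_map(image_id).values_at(pts))
    if schema.use_xy:
        h, w = shape
        cols.append(pts[:, 0] / w)
        cols.append(pts[:, 1] / h)
    return np.column_stack(cols)


def build_training_set(judgments: PointTable, maps: dict[str, dict[str, SaliencyMap]],
                       fixations: PointTable | None, schema: FeatureSchema,
                       n_neg_per_image: int = 100, seed: int = 0,
                       exclusion_radius: float = 0.0,
                       image_ids: list[str] | None = None) -> TrainingSet:
    """Assemble the labelled feature matrix over the given images.

    Positives: every explicit-judgment point (label 1).  Negatives:
    ``n_neg_per_image`` seeded uniform pixel draws per image, excluding
    positive pixels (and, optionally, a radius around them), label 0.
    """
    if image_ids is None:
        image_ids = judgments.image_ids(task="explicit_judgment")
    if not image_ids:
        raise ValidationError("no image with explicit-judgment points")
    feats, labels, prov = [], [], []
    for i, image_id in enumerate(sorted(image_ids)):
        pos = judgments.points(image_id=image_id, task="explicit_judgment")
        if len(pos) == 0:
            raise ValidationError(f"image {image_id!r} has no explicit-judgment points")
        some_alg = schema.algorithm_ids[0] if schema.algorithm_ids else None
        if some_alg is not None:
            if image_id not in maps.get(some_alg, {}):
                raise ValidationError(
                    f"algorithm {some_alg!r} has no map for image {image_id!r}")
            shape = maps[some_alg][image_id].shape
        else:
            shape = (int(pos[:, 1].max()) + 1, int(pos[:, 0].max()) + 1)
        h, w = shape
        pos_lin = np.unique(pos[:, 1] * w + pos[:, 0])
        if exclusion_radius > 0:
            yy, xx = np.mgrid[0:h, 0:w]
            d2 = np.full(shape, np.inf)
            for px, py in np.unique(pos, axis=0):
                d2 = np.minimum(d2, (xx - px) ** 2 + (yy - py) ** 2)
            allowed = np.nonzero(d2.ravel() > exclusion_radius ** 2)[0]
        else:
            allowed = np.setdiff1d(np.arange(h * w), pos_lin)
        if len(allowed) < n_neg_per_image:
            raise ValidationError(f"image {image_id!r}: not enough negative candidates")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11, i]))
        neg_lin = rng.choice(allowed, size=n_neg_per_image, replace=False)
        neg = np.column_stack([neg_lin % w, neg_lin // w])
        pts = np.vstack([pos, neg])
        feats.append(_pixel_features(image_id, pts, maps, fixations, schema, shape))
        labels.append(np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]))
        prov.extend((image_id, int(p[0]), int(p[1])) for p in pts)
    return TrainingSet(features=np.vstack(feats), labels=np.concatenate(labels),
                       provenance=prov, schema=schema, image_ids=sorted(image_ids))


def train(ts: TrainingSet, n_trees: int = 15, seed: int = 0) -> JudgmentPredictor:
    """Fit bagged regression trees (bootstrap per tree, sqrt-feature splits)."""
    classes = np.unique(ts.labels)
    if len(classes) < 2:
        raise ValidationError("training set must contain both labels")
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed) % 2**31,
        n_jobs=1,
    )
    model.fit(ts.features, ts.labels)
    return JudgmentPredictor(model=model, schema=ts.schema, n_trees=n_trees,
                             seed=int(seed), train_image_ids=list(ts.image_ids))


def predict_map(predictor: JudgmentPredictor, image_id: str,
                maps: dict[str, dict[str, SaliencyMap]],
                fixations: PointTable | None, shape: tuple[int, int],
                blur_level: int = 4) -> SaliencyMap:
    """Predicted explicit-judgment map over the full grid.

    Per-pixel model output is clamped to [0, 1], Gaussian blurred at
    ``blur_level`` (0 = no smoothing), and min-max rescaled to [0, 1].
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    feats = _pixel_features(image_id, pts, maps, fixations, predictor.schema, shape)
    if feats.shape[1] != predictor.schema.n_features:
        raise ValidationError("feature matrix does not match predictor schema")
    pred = np.clip(predictor.model.predict(feats), 0.0, 1.0).reshape(shape)
    if blur_level > 0:
        pred = gaussian_filter(pred, sigma=blur_sigma(blur_level, shape,
                                                      predictor.schema.sigma_per_level))
    lo, hi = pred.min(), pred.max()
    if hi > lo:
        pred = (pred - lo) / (hi - lo)
    return SaliencyMap(image_id, pred, algorithm_id="judgment_predictor")


def evaluate_predictor(predictor: JudgmentPredictor, judgments: PointTable,
                       maps: dict[str, dict[str, SaliencyMap]],
                       fixations: PointTable | None, shape: tuple[int, int],
                       test_image_ids: list[str], metric: str = "standard",
                       blur_level: int = 4, seed: int = 0,
                       n_neg_ratio: float = 5.0) -> tuple[float, dict[str, RocResult]]:
    """Per-test-image AUC of predicted maps against true judgments, + mean.

    Refuses to run if any test image was seen during training.
    """
    overlap = set(test_image_ids) & set(predictor.train_image_ids)
    if overlap:
        raise ValidationError(f"train/test image overlap: {sorted(overlap)}")
    results: dict[str, RocResult] = {}
    for i, image_id in enumerate(sorted(test_image_ids)):
        smap = predict_map(predictor, image_id, maps, fixations, shape, blur_level)
        positives = judgments.points(image_id=image_id, task="explicit_judgment")
        s = int(np.random.SeedSequence([int(seed), 13, i]).generate_state(1)[0] % 2**31)
        if metric == "standard":
            results[image_id] = standard_auc(smap, positives, n_neg_ratio=n_neg_ratio, seed=s)
        elif metric == "shuffled":
            pool = shuffled_pool(judgments, image_id, "explicit_judgment")
            results[image_id] = shuffled_auc(smap, positives, pool, seed=s)
        else:
            raise ValidationError(f"unknown metric {metric!r}")
    mean = float(np.mean([r.auc for r in results.values()]))
    return mean, results


def save_predictor(predictor: JudgmentPredictor, path) -> None:
    """Serialize model + schema + seed + training provenance to one archive."""
    payload = {
        "model": predictor.model,
        "schema": asdict(predictor.schema),
        "n_trees": predictor.n_trees,
        "seed": predictor.seed,
        "train_image_ids": predictor.train_image_ids,
    }
    joblib.dump(payload, path)


def load_predictor(path) -> JudgmentPredictor:
    payload = joblib.load(path)
    return JudgmentPredictor(
        model=payload["model"],
        schema=FeatureSchema(**payload["schema"]),
        n_trees=payload["n_trees"],
        seed=payload["seed"],
        train_image_ids=payload["train_image_ids"],
    )
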