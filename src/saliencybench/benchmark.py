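"""Dataset-level benchmarking: per-image and mean AUC tables per algorithm.

The shuffled negative pool for an image is the union of same-task points
selected on every *other* image of the dataset (coordinates reused on the
scored image), which matches the dataset-wide spatial distribution of the
data while excluding the image's own positives.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MapEnsemble, PointTable, SaliencyMap, ValidationError
from .metrics import shuffled_auc, standard_auc
from . import bias as bias_mod


def _image_seed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, keys)]).generate_state(1)[0] % 2**31)


def shuffled_pool(table: PointTable, image_id: str, task: str) -> np.ndarray:
    """Same-task points from all other images."""
    sub = table.frame
    m = (sub["task"] == task) & (sub["image_id"] != image_id)
    return sub.loc[m, ["x", "y"]].to_numpy(dtype=np.int64)


def mean_auc(maps_by_image: dict[str, SaliencyMap], table: PointTable, task: str,
             metric: str = "standard", seed: int = 0, n_neg_ratio: float = 5.0,
             max_neg_ratio: float = 10.0,
             image_ids: list[str] | None = None) -> tuple[float, dict[str, float]]:
    """Mean over images of per-image AUC of one algorithm's maps.

    Positives for an image are all its same-task points pooled over
    observers (multiplicity kept).  ``metric`` selects the negative-sampling
    scheme: "standard" (uniform) or "shuffled" (dataset pool).
    """
    if metric not in ("standard", "shuffled"):
        raise ValidationError(f"unknown metric {metric!r}")
    if image_ids is None:
        image_ids = sorted(set(table.image_ids(task=task)) & set(maps_by_image))
    if not image_ids:
        raise ValidationError(f"no image with both a map and {task!r} points")
    per_image: dict[str, float] = {}
    for i, image_id in enumerate(sorted(image_ids)):
        smap = maps_by_image[image_id]
        positives = table.points(image_id=image_id, task=task)
        if len(positives) == 0:
            continue
        s = _image_seed(seed, i)
        if metric == "standard":
            res = standard_auc(smap, positives, n_neg_ratio=n_neg_ratio, seed=s)
        else:
            pool = shuffled_pool(table, image_id, task)
            res = shuffled_auc(smap, positives, pool, seed=s, max_neg_ratio=max_neg_ratio)
        per_image[image_id] = res.auc
    return float(np.mean(list(per_image.values()))), per_image


def benchmark_algorithms(maps: dict[str, dict[str, SaliencyMap]], table: PointTable,
                         tasks: list[str], metrics: list[str] = ("standard", "shuffled"),
                         seed: int = 0, n_neg_ratio: float = 5.0,
                         debias: str | None = None) -> pd.DataFrame:
    """Score every (algorithm, task, metric); returns a tidy DataFrame.

    ``debias`` in {None, "rank", "whiten"} applies the corresponding
    center-bias removal to each algorithm's map ensemble before scoring.
    """
    rows = []
    for aid in sorted(maps):
        by_image = maps[aid]
        if debias:
            order = sorted(by_image)
            ens = MapEnsemble(aid, [by_image[i] for i in order])
            ens = bias_mod.debias_rank(ens) if debias == "rank" else bias_mod.debias_whiten(ens)
            by_image = {m.image_id: m for m in ens.maps}
        for task in tasks:
            for metric in metrics:
                mean, per_image = mean_auc(by_image, table, task, metric=metric,
                                           seed=seed, n_neg_ratio=n_neg_ratio)
                rows.append({"algorithm_id": aid, "task": task, "metric": metric,
                             "auc": mean, "n_images": len(per_image)})
    return pd.DataFrame(rows)
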