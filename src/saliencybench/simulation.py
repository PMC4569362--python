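"""Simulating explicit-judgment data from a predicted judgment map.

A predicted explicit-judgment map is a continuous surface, but ROC-based
evaluation wants discrete selected locations.  The simulator min-max
normalizes the map, zeroes every pixel below a threshold, and draws a fixed
number of locations (default 100, matching the size of a typical
100-observer judgment pool) with replacement, with probability proportional
to the remaining values.

The threshold matters: observers asked for the *single most salient*
location concentrate on map peaks, so low-value regions of the predicted
map should contribute no samples.  The default of 0.5 on the normalized
range comes from a sensitivity sweep (see the methods note): surrogate
ranking fidelity improves monotonically with the threshold, with 0.5 giving
robust fidelity while retaining dispersion over multiple peaks.

Surrogate benchmarking then asks: if algorithms are scored against these
simulated judgments instead of real ones, do they rank the same way?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .datatypes import PointTable, SaliencyMap, ValidationError
from .metrics import pearson
from .benchmark import mean_auc


@dataclass
class SimulationConfig:
    n_points: int = 100
    threshold: float = 0.5     # on the min-max normalized map
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValidationError("n_points must be >= 1")
        if not 0 <= self.threshold < 1:
            raise ValidationError("threshold must be in [0, 1)")


def simulate_judgments(smap: SaliencyMap, cfg: SimulationConfig) -> np.ndarray:
    """Draw ``n_points`` (x, y) locations (with replacement) from the
    thresholded, renormalized map.  Returns an (n_points, 2) array;
    coincident draws are kept as multiplicity."""
    grid = smap.grid
    lo, hi = grid.min(), grid.max()
    norm = (grid - lo) / (hi - lo) if hi > lo else np.zeros_like(grid)
    weights = np.where(norm >= cfg.threshold, norm, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValidationError("thresholded map empty: no pixel above threshold")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 29]))
    h, w = grid.shape
    idx = rng.choice(h * w, size=cfg.n_points, p=weights / total, replace=True)
    return np.column_stack([idx % w, idx // w]).astype(np.int64)


def simulated_point_table(maps_by_image: dict[str, SaliencyMap],
                          cfg: SimulationConfig) -> PointTable:
    """Simulate judgments for every image; one synthetic observer per draw
    (observer_id ``sim<k>``, task ``explicit_judgment``, ordinal 0)."""
    records = []
    for i, image_id in enumerate(sorted(maps_by_image)):
        img_cfg = SimulationConfig(
            n_points=cfg.n_points, threshold=cfg.threshold,
            seed=int(np.random.SeedSequence([int(cfg.seed), 31, i]).generate_state(1)[0] % 2**31),
        )
        pts = simulate_judgments(maps_by_image[image_id], img_cfg)
        for k, (x, y) in enumerate(pts):
            records.append((image_id, f"sim{k}", "explicit_judgment", int(x), int(y), 0))
    return PointTable.from_records(records)


@dataclass
class SurrogateResult:
    algorithm_ids: list[str]
    auc_true: np.ndarray
    auc_sim: np.ndarray
    correlation: float


def surrogate_benchmark(maps: dict[str, dict[str, SaliencyMap]],
                        true_points: PointTable, sim_points: PointTable,
                        metric: str = "standard", task: str = "explicit_judgment",
                        seed: int = 0, n_neg_ratio: float = 5.0,
                        correlation: str = "pearson") -> SurrogateResult:
    """Per-algorithm mean AUC against true vs simulated judgment points, and
    the correlation between the two score vectors.

    A high correlation means the simulated data ranks algorithms like the
    real data would, so it can stand in for it in benchmarking.
    """
    if len(maps) < 3:
        raise ValidationError("surrogate benchmarking needs >= 3 algorithms")
    algorithm_ids = sorted(maps)
    auc_true, auc_sim = [], []
    for aid in algorithm_ids:
        t, _ = mean_auc(maps[aid], true_points, task, metric=metric, seed=seed,
                        n_neg_ratio=n_neg_ratio)
        s, _ = mean_auc(maps[aid], sim_points, task, metric=metric, seed=seed,
                        n_neg_ratio=n_neg_ratio)
        auc_true.append(t)
        auc_sim.append(s)
    auc_true = np.asarray(auc_true)
    auc_sim = np.asarray(auc_sim)
    if correlation == "pearson":
        corr = pearson(auc_true, auc_sim)
    elif correlation == "spearman":
        corr = float(spearmanr(auc_true, auc_sim).statistic)
    else:
        raise ValidationError(f"unknown correlation {correlation!r}")
    return SurrogateResult(algorithm_ids=algorithm_ids, auc_true=auc_true,
                           auc_sim=auc_sim, correlation=corr)
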