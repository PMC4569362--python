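"""Seed-deterministic synthetic scenes, observers, and "algorithms".

The generator emulates the structure of a multi-task saliency dataset:

* each scene has a handful of latent salient locations (a Gaussian-blob
  mixture standing in for image content);
* observers select points from a mixture of that latent salience and a
  central Gaussian, the weight of the central component depending on the
  task (free viewing is most center-biased, explicit judgment least);
* synthetic "algorithms" output the latent salience corrupted by i.i.d.
  Gaussian noise (fidelity) plus an optional injected central-bias profile,
  mimicking the spread of spatial bias found across published models;
* object masks are latent-salience level sets, for segmentation scoring.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json
import zlib

import numpy as np

from .datatypes import (
    ImageCatalog,
    MapEnsemble,
    PointTable,
    SaliencyMap,
    ValidationError,
    TASKS,
)
from . import io as sio

#: Central-mixture weight per task: free viewing carries the strongest
#: center bias, task-directed gaze less, manual explicit judgment almost none.
TASK_CENTER_BIAS = {
    "free_view": 0.5,
    "saliency_view": 0.3,
    "object_search": 0.2,
    "explicit_judgment": 0.05,
}


def _stable_hash(text: str) -> int:
    # process-independent, unlike builtin hash()
    return zlib.crc32(text.encode("utf-8"))


def _child_seed(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


@dataclass
class SceneModel:
    """Latent salient structure of one synthetic image."""

    image_id: str
    shape: tuple[int, int]           # (height, width)
    blobs: list[dict]                # {"center": (x, y), "sigma": px, "weight": w}
    latent: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.latent is None:
            self.latent = _mixture_density(self.shape, self.blobs)


@dataclass
class ObserverModel:
    """Point-selection behaviour shared by a population of observers.

    ``center_bias_weight=None`` means "use the task default" from
    :data:`TASK_CENTER_BIAS`.
    """

    center_bias_weight: float | None = None
    center_sigma: float = 0.15        # fraction of max(image dims)
    point_jitter: float = 1.0         # SD of rounding jitter, pixels
    n_points_per_task: int = 10

    def __post_init__(self) -> None:
        if self.center_bias_weight is not None and not 0 <= self.center_bias_weight <= 1:
            raise ValidationError("center_bias_weight must be in [0, 1]")


@dataclass
class AlgorithmModel:
    """A synthetic saliency algorithm: latent signal + noise + spatial bias."""

    algorithm_id: str
    fidelity_noise_sd: float = 0.3    # relative to a latent peak of 1
    injected_bias: np.ndarray | None = None   # zero-mean grid, or None

    def __post_init__(self) -> None:
        if not np.isfinite(self.fidelity_noise_sd) or self.fidelity_noise_sd < 0:
            raise ValidationError("fidelity_noise_sd must be finite and >= 0")


def _mixture_density(shape: tuple[int, int], blobs: list[dict]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.zeros(shape, dtype=float)
    for blob in blobs:
        bx, by = blob["center"]
        s = blob["sigma"]
        grid += blob["weight"] * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * s * s))
    total = grid.sum()
    if total <= 0:
        raise ValidationError("degenerate latent density")
    return grid / total


def central_bias_grid(shape: tuple[int, int], amplitude: float,
                      sigma_frac: float = 0.2) -> np.ndarray:
    """Zero-mean centered-Gaussian profile used as injected algorithm bias."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    s = sigma_frac * max(shape)
    g = amplitude * np.exp(-(((xx - (w - 1) / 2) ** 2) + ((yy - (h - 1) / 2) ** 2)) / (2 * s * s))
    return g - g.mean()


def gen_scene(shape: tuple[int, int], n_blobs: int, seed: int,
              image_id: str | None = None) -> SceneModel:
    """Place ``n_blobs`` Gaussian blobs with a margin from the borders."""
    if n_blobs < 1:
        raise ValidationError("n_blobs must be >= 1")
    h, w = shape
    margin = max(3, min(h, w) // 8)
    if 2 * margin >= min(h, w):
        raise ValidationError(f"shape {shape} too small for blob margin {margin}")
    rng = _child_seed(seed, 0)
    size = max(shape)
    blobs = []
    for _ in range(n_blobs):
        blobs.append({
            "center": (int(rng.integers(margin, w - margin)),
                       int(rng.integers(margin, h - margin))),
            "sigma": float(rng.uniform(0.05, 0.09) * size),
            "weight": float(rng.uniform(0.5, 1.0)),
        })
    return SceneModel(image_id=image_id or f"scene{seed}", shape=shape, blobs=blobs)


def _sample_from_density(rng: np.random.Generator, density: np.ndarray, n: int) -> np.ndarray:
    h, w = density.shape
    idx = rng.choice(h * w, size=n, p=density.ravel() / density.sum())
    return np.column_stack([idx % w, idx // w])   # (x, y)


def gen_points(scene: SceneModel, observer: ObserverModel, task: str,
               n_observers: int, seed: int) -> PointTable:
    """Draw each observer's points from (1-w)·latent + w·central Gaussian.

    ``w`` is the observer's center-bias weight (task default if unset).
    Integer-rounded Gaussian jitter is added and points are clipped to the
    grid.  Explicit-judgment observers select a single point (ordinal 0);
    gaze tasks produce ``n_points_per_task`` ordered fixations.
    """
    if task not in TASKS:
        raise ValidationError(f"unknown task {task!r}")
    w_center = (TASK_CENTER_BIAS[task] if observer.center_bias_weight is None
                else observer.center_bias_weight)
    h, w = scene.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    c_sigma = observer.center_sigma * max(scene.shape)
    n_points = 1 if task == "explicit_judgment" else observer.n_points_per_task
    records = []
    for obs_idx in range(n_observers):
        rng = _child_seed(seed, _stable_hash(task), obs_idx)
        for ordinal in range(n_points):
            if rng.random() < w_center:
                x = cx + rng.normal(0, c_sigma)
                y = cy + rng.normal(0, c_sigma)
            else:
                pt = _sample_from_density(rng, scene.latent, 1)[0]
                x, y = float(pt[0]), float(pt[1])
            if observer.point_jitter > 0:
                x += rng.normal(0, observer.point_jitter)
                y += rng.normal(0, observer.point_jitter)
            xi = int(np.clip(round(x), 0, w - 1))
            yi = int(np.clip(round(y), 0, h - 1))
            records.append((scene.image_id, f"obs{obs_idx}", task, xi, yi, ordinal))
    return PointTable.from_records(records)


def gen_algorithm_maps(scenes: list[SceneModel], model: AlgorithmModel,
                       seed: int) -> MapEnsemble:
    """One map per scene: peak-normalized latent + noise + injected bias,
    min-max rescaled to [0, 1]."""
    maps = []
    for i, scene in enumerate(scenes):
        rng = _child_seed(seed, _stable_hash(model.algorithm_id), i)
        grid = scene.latent / scene.latent.max()
        if model.fidelity_noise_sd > 0:
            grid = grid + rng.normal(0, model.fidelity_noise_sd, size=scene.shape)
        if model.injected_bias is not None:
            grid = grid + model.injected_bias
        lo, hi = grid.min(), grid.max()
        grid = (grid - lo) / (hi - lo) if hi > lo else np.zeros_like(grid)
        maps.append(SaliencyMap(scene.image_id, grid, model.algorithm_id))
    return MapEnsemble(model.algorithm_id, maps)


def gen_masks(scene: SceneModel, level: float) -> np.ndarray:
    """Binary object mask: latent salience at or above ``level``·max."""
    if not 0 < level < 1:
        raise ValidationError("mask level must be in (0, 1)")
    mask = scene.latent >= level * scene.latent.max()
    if not mask.any():
        raise ValidationError("mask is empty")
    return mask


def default_algorithm_models(shape: tuple[int, int]) -> list[AlgorithmModel]:
    """Six synthetic algorithms spanning fidelity and center-bias levels."""
    cb = lambda amp: central_bias_grid(shape, amp)
    return [
        AlgorithmModel("hifi_unbiased", 0.15, None),
        AlgorithmModel("hifi_slightbias", 0.20, cb(0.25)),
        AlgorithmModel("midfi_unbiased", 0.35, None),
        AlgorithmModel("midfi_center", 0.35, cb(0.6)),
        AlgorithmModel("lofi_unbiased", 0.70, None),
        AlgorithmModel("lofi_center", 0.70, cb(1.0)),
    ]


def extended_algorithm_models(shape: tuple[int, int]) -> list[AlgorithmModel]:
    """Twelve synthetic algorithms: four fidelity levels, each in an
    unbiased, centrally biased, and peripherally biased variant.

    Published saliency models span exactly this range — some emphasize the
    center regardless of content, others the periphery — and benchmarking
    studies typically compare on the order of a dozen of them, so the
    surrogate-benchmarking experiments use this roster.
    """
    out = []
    for i, sd in enumerate([0.15, 0.3, 0.5, 0.75]):
        out.append(AlgorithmModel(f"a{3 * i:02d}_sd{sd}_unbiased", sd, None))
        out.append(AlgorithmModel(f"a{3 * i + 1:02d}_sd{sd}_central", sd,
                                  central_bias_grid(shape, 0.9)))
        out.append(AlgorithmModel(f"a{3 * i + 2:02d}_sd{sd}_peripheral", sd,
                                  central_bias_grid(shape, -0.9)))
    return out


@dataclass
class ScenarioConfig:
    """Study conditions for a full synthetic benchmark dataset."""

    n_images: int = 20
    shape: tuple[int, int] = (64, 64)
    n_blobs: int = 3
    n_observers: int = 10            # per gaze task, 10 fixations each
    n_ej_observers: int = 100        # explicit judgment: one pick each
    points_per_observer: int = 10
    center_sigma: float = 0.15
    point_jitter: float = 1.0
    mask_level: float = 0.5
    algorithms: list[AlgorithmModel] | None = None

    def resolved_algorithms(self) -> list[AlgorithmModel]:
        if self.algorithms is not None:
            return self.algorithms
        return default_algorithm_models(tuple(self.shape))


@dataclass
class Scenario:
    """In-memory synthetic dataset: scenes, points, maps, masks."""

    config: ScenarioConfig
    seed: int
    scenes: list[SceneModel]
    catalog: ImageCatalog
    points: PointTable
    ensembles: dict[str, MapEnsemble]
    masks: dict[str, np.ndarray]

    def maps_by_image(self, algorithm_id: str) -> dict[str, SaliencyMap]:
        return {m.image_id: m for m in self.ensembles[algorithm_id].maps}


def gen_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Generate the full synthetic study in memory (pure in config and seed)."""
    config = config or ScenarioConfig()
    shape = tuple(config.shape)
    scenes = [
        gen_scene(shape, config.n_blobs,
                  seed=int(np.random.SeedSequence([seed, 1, i]).generate_state(1)[0] % 2**31),
                  image_id=f"img{i:03d}")
        for i in range(config.n_images)
    ]
    observer = ObserverModel(center_sigma=config.center_sigma,
                             point_jitter=config.point_jitter,
                             n_points_per_task=config.points_per_observer)
    tables = []
    for t_idx, task in enumerate(TASKS):
        n_obs = config.n_ej_observers if task == "explicit_judgment" else config.n_observers
        for i, scene in enumerate(scenes):
            tables.append(gen_points(
                scene, observer, task, n_obs,
                seed=int(np.random.SeedSequence([seed, 2, t_idx, i]).generate_state(1)[0] % 2**31),
            ))
    points = PointTable.concat(tables)
    ensembles = {
        model.algorithm_id: gen_algorithm_maps(
            scenes, model,
            seed=int(np.random.SeedSequence([seed, 3, a]).generate_state(1)[0] % 2**31))
        for a, model in enumerate(config.resolved_algorithms())
    }
    masks = {s.image_id: gen_masks(s, config.mask_level) for s in scenes}
    catalog = ImageCatalog({s.image_id: (shape[1], shape[0]) for s in scenes})
    return Scenario(config=config, seed=seed, scenes=scenes, catalog=catalog,
                    points=points, ensembles=ensembles, masks=masks)


def _config_manifest(config: ScenarioConfig) -> dict:
    d = asdict(config)
    d["shape"] = list(config.shape)
    if config.algorithms is not None:
        d["algorithms"] = [
            {"algorithm_id": a.algorithm_id,
             "fidelity_noise_sd": a.fidelity_noise_sd,
             "has_injected_bias": a.injected_bias is not None}
            for a in config.algorithms
        ]
    return d


def gen_benchmark_scenario(config: ScenarioConfig | None = None, seed: int = 0,
                           out_dir=None) -> Scenario:
    """Generate a scenario and write it to disk in the package formats.

    Layout: ``catalog.json``, ``points.csv``, ``maps/<alg>/<image>.png``
    (16-bit), ``masks/<image>.png``, and a ``manifest.json`` recording every
    parameter and the seed.
    """
    scenario = gen_scenario(config, seed)
    if out_dir is None:
        return scenario
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_catalog(scenario.catalog, out / "catalog.json")
    sio.write_point_table(scenario.points, out / "points.csv")
    for aid, ens in scenario.ensembles.items():
        for m in ens.maps:
            sio.write_map(m, out / "maps" / aid / f"{m.image_id}.png", depth=16)
    for image_id, mask in scenario.masks.items():
        sio.write_mask(mask, out / "masks" / f"{image_id}.png")
    manifest = {"seed": int(seed), "config": _config_manifest(scenario.config),
                "algorithms": sorted(scenario.ensembles)}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return scenario


@dataclass
class BenchmarkData:
    """A scenario re-loaded from disk (maps keyed algorithm -> image)."""

    catalog: ImageCatalog
    points: PointTable
    maps: dict[str, dict[str, SaliencyMap]]
    masks: dict[str, np.ndarray]


def load_benchmark_scenario(data_dir) -> BenchmarkData:
    """Load a dataset written by :func:`gen_benchmark_scenario`.

    Raises :class:`FileNotFoundError` naming the algorithm and image if any
    expected map file is missing.
    """
    data_dir = Path(data_dir)
    catalog = sio.read_catalog(data_dir / "catalog.json")
    points = sio.read_point_table(data_dir / "points.csv", catalog)
    maps: dict[str, dict[str, SaliencyMap]] = {}
    maps_root = data_dir / "maps"
    if maps_root.is_dir():
        for alg_dir in sorted(p for p in maps_root.iterdir() if p.is_dir()):
            aid = alg_dir.name
            maps[aid] = {}
            for image_id in catalog.image_ids:
                path = alg_dir / f"{image_id}.png"
                if not path.exists():
                    raise FileNotFoundError(
                        f"missing map for algorithm {aid!r}, image {image_id!r}: {path}"
                    )
                maps[aid][image_id] = sio.read_map(path, image_id, aid)
    masks = {}
    masks_root = data_dir / "masks"
    if masks_root.is_dir():
        for image_id in catalog.image_ids:
            path = masks_root / f"{image_id}.png"
            if path.exists():
                masks[image_id] = sio.read_mask(path)
    return BenchmarkData(catalog=catalog, points=points, maps=maps, masks=masks)
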