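"""Prepackaged end-to-end experiments on the synthetic scenario.

These compose the library modules into the studies a user would typically
run: de-biased benchmarking agreement, ranking-fairness recovery, ensemble
predictor evaluation, and surrogate benchmarking with simulated
explicit-judgment data.  Each is a pure function of its seed (plus optional
config) and returns plain dictionaries of numbers.
"""

from __future__ import annotations

import numpy as np

from .benchmark import benchmark_algorithms, mean_auc
from .bias import debias_rank
from .datatypes import PointTable
from .metrics import pearson
from .metrics import mann_whitney_auc
from .prediction import (
    FeatureSchema,
    TrainingSet,
    build_training_set,
    evaluate_predictor,
    predict_map,
    split_images,
    train,
)
from .simulation import SimulationConfig, simulated_point_table, surrogate_benchmark
from .synth import (
    AlgorithmModel,
    ScenarioConfig,
    central_bias_grid,
    extended_algorithm_models,
    gen_scenario,
)


def debias_agreement(seed: int, task: str = "free_view") -> dict:
    """Standard vs shuffled AUC per algorithm after rank de-biasing.

    With the per-pixel value distribution equalized across maps, the two
    negative-sampling schemes should agree closely even on the most
    center-biased task.
    """
    sc = gen_scenario(seed=seed)
    maps = {aid: sc.maps_by_image(aid) for aid in sc.ensembles}
    table = benchmark_algorithms(maps, sc.points, tasks=[task], seed=seed,
                                 debias="rank")
    pivot = table.pivot(index="algorithm_id", columns="metric", values="auc")
    diffs = (pivot["standard"] - pivot["shuffled"]).abs()
    return {
        "per_algorithm": pivot.to_dict("index"),
        "max_abs_diff": float(diffs.max()),
    }


def ranking_fairness(seed: int) -> dict:
    """Raw vs de-biased standard AUC for a biased/low-fidelity algorithm
    against an unbiased/high-fidelity one, on free-viewing data.

    The biased model rides the data's center bias to a higher raw score;
    rank de-biasing restores the fidelity ordering.
    """
    shape = (64, 64)
    algorithms = [
        AlgorithmModel("biased_lofi", 0.45, central_bias_grid(shape, 1.2)),
        AlgorithmModel("clean_hifi", 0.15, None),
    ]
    sc = gen_scenario(ScenarioConfig(algorithms=algorithms), seed=seed)
    out: dict = {}
    for label, debias in (("raw", False), ("debiased", True)):
        out[label] = {}
        for aid, ens in sc.ensembles.items():
            if debias:
                ens = debias_rank(ens)
            by_image = {m.image_id: m for m in ens.maps}
            auc, _ = mean_auc(by_image, sc.points, "free_view", seed=seed + 1)
            out[label][aid] = auc
    return out


def predictor_experiment(seed: int, n_trees: int = 15, blur_level: int = 4) -> dict:
    """Train the judgment predictor on half the images, score on the rest.

    Reports the ensemble's held-out standard AUC, each single algorithm's
    AUC on the same test images, and the gain over the best single map.
    """
    sc = gen_scenario(seed=seed)
    maps = {aid: sc.maps_by_image(aid) for aid in sc.ensembles}
    schema = FeatureSchema(algorithm_ids=sorted(maps))
    train_ids, test_ids = split_images(
        sc.points.image_ids(task="explicit_judgment"), seed)
    ts = build_training_set(sc.points, maps, sc.points, schema, seed=seed,
                            image_ids=train_ids)
    predictor = train(ts, n_trees=n_trees, seed=seed)
    ensemble_auc, _ = evaluate_predictor(
        predictor, sc.points, maps, sc.points, tuple(sc.config.shape),
        test_ids, metric="standard", blur_level=blur_level, seed=seed + 1)
    singles = {}
    for aid in maps:
        singles[aid], _ = mean_auc(maps[aid], sc.points, "explicit_judgment",
                                   seed=seed + 1, image_ids=test_ids)
    best = max(singles.values())

    # Null control: the same regressor trained on permuted labels must not
    # discriminate held-out positives from negatives.
    held = build_training_set(sc.points, maps, sc.points, schema, seed=seed + 1,
                              image_ids=test_ids)
    perm = np.random.default_rng(seed + 100).permutation(len(ts.labels))
    null_model = train(
        TrainingSet(ts.features, ts.labels[perm], ts.provenance, schema,
                    ts.image_ids),
        n_trees=n_trees, seed=seed)
    null_pred = null_model.model.predict(held.features)
    permuted_auc = mann_whitney_auc(null_pred[held.labels == 1],
                                    null_pred[held.labels == 0])

    # Bagging: averaging many trees should not score below a single tree.
    tree_auc = {}
    for k in (1, 50):
        model_k = train(ts, n_trees=k, seed=seed)
        tree_auc[k], _ = evaluate_predictor(
            model_k, sc.points, maps, sc.points, tuple(sc.config.shape),
            test_ids, metric="standard", blur_level=blur_level, seed=seed + 1)

    return {
        "ensemble_auc": ensemble_auc,
        "single_algorithm_auc": singles,
        "best_single_auc": best,
        "gain": ensemble_auc - best,
        "permuted_label_auc": permuted_auc,
        "auc_1_tree": tree_auc[1],
        "auc_50_trees": tree_auc[50],
        "train_image_ids": train_ids,
        "test_image_ids": test_ids,
    }


def surrogate_experiment(seed: int, n_trees: int = 15, blur_level: int = 4,
                         sim_config: SimulationConfig | None = None) -> dict:
    """Full simulation pipeline on the 12-model roster.

    Trains the predictor on half the images, predicts judgment maps for the
    other half, samples simulated judgment points from them, and compares
    per-algorithm AUC rankings: simulated-vs-true judgments, and (as the
    baseline) free-viewing fixations-vs-true judgments.
    """
    shape = (64, 64)
    cfg = ScenarioConfig(algorithms=extended_algorithm_models(shape))
    sc = gen_scenario(cfg, seed=seed)
    maps = {aid: sc.maps_by_image(aid) for aid in sc.ensembles}
    schema = FeatureSchema(algorithm_ids=sorted(maps))
    train_ids, test_ids = split_images(
        sc.points.image_ids(task="explicit_judgment"), seed)
    ts = build_training_set(sc.points, maps, sc.points, schema, seed=seed,
                            image_ids=train_ids)
    predictor = train(ts, n_trees=n_trees, seed=seed)
    pred_maps = {
        iid: predict_map(predictor, iid, maps, sc.points, shape, blur_level)
        for iid in test_ids
    }
    if sim_config is None:
        sim_config = SimulationConfig(seed=seed + 2)
    sim_table = simulated_point_table(pred_maps, sim_config)
    frame = sc.points.frame
    true_table = PointTable(frame[
        (frame["task"] == "explicit_judgment") & frame["image_id"].isin(test_ids)
    ].reset_index(drop=True))
    test_maps = {aid: {i: maps[aid][i] for i in test_ids} for aid in maps}
    result = surrogate_benchmark(test_maps, true_table, sim_table, seed=seed + 3)
    auc_fix = np.array([
        mean_auc(maps[aid], sc.points, "free_view", seed=seed + 3,
                 image_ids=test_ids)[0]
        for aid in result.algorithm_ids
    ])
    return {
        "algorithm_ids": result.algorithm_ids,
        "auc_true": result.auc_true.tolist(),
        "auc_sim": result.auc_sim.tolist(),
        "auc_fixation": auc_fix.tolist(),
        "corr_sim_true": result.correlation,
        "corr_fixation_true": pearson(auc_fix, result.auc_true),
    }
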