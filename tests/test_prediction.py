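import numpy as np
import pytest

import saliencybench as sb
from saliencybench.datatypes import SaliencyMap, ValidationError
from saliencybench import prediction as P


@pytest.fixture(scope="module")
def small_setup():
    """3 synthetic algorithms over 4 images, with judgments and fixations."""
    sc = sb.gen_scenario(sb.ScenarioConfig(
        n_images=4, n_ej_observers=50,
        algorithms=[sb.AlgorithmModel(f"alg{i}", 0.2 + 0.2 * i) for i in range(3)],
    ), seed=5)
    maps = {aid: sc.maps_by_image(aid) for aid in sc.ensembles}
    return sc, maps


class TestSplit:
    def test_even_and_odd_counts(self):
        train, test = P.split_images([f"i{k}" for k in range(4)], seed=0)
        assert len(train) == 2 and len(test) == 2
        train, test = P.split_images([f"i{k}" for k in range(5)], seed=0)
        assert len(train) == 3 and len(test) == 2
        assert not set(train) & set(test)

    def test_deterministic(self):
        ids = [f"i{k}" for k in range(9)]
        assert P.split_images(ids, seed=3) == P.split_images(ids, seed=3)
        assert P.split_images(ids, seed=3) != P.split_images(ids, seed=4)

    def test_too_few_error(self):
        with pytest.raises(ValidationError):
            P.split_images(["only"], seed=0)


class TestTrainingSet:
    def test_matrix_shape_full_schema(self, small_setup):
        sc, maps = small_setup
        schema = P.FeatureSchema(algorithm_ids=sorted(maps))
        ts = P.build_training_set(sc.points, maps, sc.points, schema,
                                  n_neg_per_image=50, seed=0, image_ids=["img000"])
        # 50 judgment positives + 50 negatives; 3 maps + density + (x, y)
        assert ts.features.shape == (100, 6)
        assert ts.labels.sum() == 50

    def test_matrix_shape_saliency_only(self, small_setup):
        sc, maps = small_setup
        schema = P.FeatureSchema(algorithm_ids=sorted(maps),
                                 use_fixation_density=False, use_xy=False)
        ts = P.build_training_set(sc.points, maps, sc.points, schema,
                                  n_neg_per_image=50, seed=0, image_ids=["img000"])
        assert ts.features.shape == (100, 3)

    def test_features_are_grid_lookups(self):
        rng = np.random.default_rng(8)
        grid = rng.random((8, 8))
        maps = {"a": {"im": SaliencyMap("im", grid, "a")}}
        judgments = sb.PointTable.from_records(
            [("im", f"o{k}", "explicit_judgment", k, 7 - k, 0) for k in range(5)])
        schema = P.FeatureSchema(["a"], use_fixation_density=False, use_xy=True)
        ts = P.build_training_set(judgments, maps, None, schema,
                                  n_neg_per_image=5, seed=1)
        for row, (image_id, x, y) in zip(ts.features, ts.provenance):
            assert row[0] == grid[y, x]
            assert row[1] == x / 8 and row[2] == y / 8

    def test_no_row_is_both_labels(self, small_setup):
        sc, maps = small_setup
        schema = P.FeatureSchema(algorithm_ids=sorted(maps))
        ts = P.build_training_set(sc.points, maps, sc.points, schema, seed=0)
        seen = {}
        for key, label in zip(ts.provenance, ts.labels):
            assert seen.setdefault(key, label) == label

    def test_missing_map_error(self, small_setup):
        sc, maps = small_setup
        schema = P.FeatureSchema(algorithm_ids=["ghost"])
        with pytest.raises(ValidationError, match="ghost"):
            P.build_training_set(sc.points, maps, sc.points, schema, seed=0)

    def test_deterministic(self, small_setup):
        sc, maps = small_setup
        schema = P.FeatureSchema(algorithm_ids=sorted(maps))
        a = P.build_training_set(sc.points, maps, sc.points, schema, seed=9)
        b = P.build_training_set(sc.points, maps, sc.points, schema, seed=9)
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)


def _toy_training_set(rng, n=400, label_from_feature=True, seed_perm=0):
    feats = rng.random((n, 4))
    labels = (feats[:, 0] > 0.5).astype(float)
    if not label_from_feature:
        perm = np.random.default_rng(seed_perm).permutation(n)
        labels = labels[perm]
    schema = P.FeatureSchema([f"f{i}" for i in range(4)],
                             use_fixation_density=False, use_xy=False)
    return P.TrainingSet(feats, labels, [("im", 0, 0)] * n, schema, ["im"])


class TestTrain:
    def test_single_class_error(self, rng):
        ts = _toy_training_set(rng)
        ts.labels[:] = 1.0
        with pytest.raises(ValidationError):
            P.train(ts, seed=0)

    def test_self_predictable_labels_recovered(self, rng):
        ts = _toy_training_set(rng)
        model = P.train(ts, n_trees=15, seed=0)
        held = rng.random((300, 4))
        pred = model.model.predict(held)
        auc = sb.mann_whitney_auc(pred[held[:, 0] > 0.5], pred[held[:, 0] <= 0.5])
        assert auc >= 0.95

    def test_permuted_labels_are_near_chance(self, rng):
        # the null width is set by chance label-feature association in the
        # training draw (~1/sqrt(n_train)), not by evaluation noise
        ts = _toy_training_set(rng, n=3000, label_from_feature=False)
        model = P.train(ts, n_trees=15, seed=0)
        held = rng.random((3000, 4))
        pred = model.model.predict(held)
        auc = sb.mann_whitney_auc(pred[held[:, 0] > 0.5], pred[held[:, 0] <= 0.5])
        assert abs(auc - 0.5) < 0.1

    def test_more_trees_do_not_hurt(self, rng):
        feats = rng.random((400, 4))
        noisy = (feats[:, 0] + rng.normal(0, 0.5, 400) > 0.5).astype(float)
        schema = P.FeatureSchema([f"f{i}" for i in range(4)],
                                 use_fixation_density=False, use_xy=False)
        ts = P.TrainingSet(feats, noisy, [("im", 0, 0)] * 400, schema, ["im"])
        held = rng.random((500, 4))
        truth = held[:, 0] > 0.5
        aucs = {}
        for n_trees in (1, 50):
            pred = P.train(ts, n_trees=n_trees, seed=3).model.predict(held)
            aucs[n_trees] = sb.mann_whitney_auc(pred[truth], pred[~truth])
        assert aucs[50] >= aucs[1]


class TestPredictMap:
    def test_constant_features_give_constant_map(self):
        maps = {"a": {"im": SaliencyMap("im", np.full((6, 6), 0.4), "a")}}
        schema = P.FeatureSchema(["a"], use_fixation_density=False, use_xy=False)
        rng = np.random.default_rng(0)
        ts = P.TrainingSet(rng.random((50, 1)), (rng.random(50) > 0.5).astype(float),
                           [("tr", 0, 0)] * 50, schema, ["tr"])
        predictor = P.train(ts, seed=0)
        out = P.predict_map(predictor, "im", maps, None, (6, 6), blur_level=0)
        assert np.ptp(out.grid) == 0.0

    def test_blur_zero_keeps_argmax_of_driving_feature(self, small_setup):
        sc, maps = small_setup
        schema = P.FeatureSchema(algorithm_ids=sorted(maps))
        train_ids, test_ids = P.split_images(sc.catalog.image_ids, seed=2)
        ts = P.build_training_set(sc.points, maps, sc.points, schema, seed=2,
                                  image_ids=train_ids)
        predictor = P.train(ts, n_trees=15, seed=2)
        out = P.predict_map(predictor, test_ids[0], maps, sc.points,
                            (64, 64), blur_level=0)
        assert out.shape == (64, 64)
        assert out.grid.min() >= 0.0 and out.grid.max() <= 1.0

    def test_evaluate_rejects_train_test_overlap(self, small_setup):
        sc, maps = small_setup
        schema = P.FeatureSchema(algorithm_ids=sorted(maps))
        ts = P.build_training_set(sc.points, maps, sc.points, schema, seed=0,
                                  image_ids=["img000", "img001"])
        predictor = P.train(ts, seed=0)
        with pytest.raises(ValidationError, match="overlap"):
            P.evaluate_predictor(predictor, sc.points, maps, sc.points,
                                 (64, 64), ["img001"], seed=0)


def test_predictor_round_trips_through_archive(tmp_path, small_setup, rng):
    sc, maps = small_setup
    schema = P.FeatureSchema(algorithm_ids=sorted(maps))
    ts = P.build_training_set(sc.points, maps, sc.points, schema, seed=1,
                              image_ids=["img000", "img001"])
    predictor = P.train(ts, seed=1)
    path = tmp_path / "model.joblib"
    P.save_predictor(predictor, path)
    back = P.load_predictor(path)
    assert back.schema == predictor.schema
    assert back.train_image_ids == predictor.train_image_ids
    probe = rng.random((10, predictor.schema.n_features))
    assert np.array_equal(back.model.predict(probe), predictor.model.predict(probe))
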