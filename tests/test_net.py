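import numpy as np
import pandas as pd
import pytest

from catres.conservation import AA_ORDER
from catres.evaluation import confusion_counts, matthews_cc
from catres.fixtures import planted_scan_tables
from catres.net import (
    CatalyticNetClassifier,
    TrainingConfig,
    balanced_sample,
    encode_features,
    encode_table,
    load_model,
    predict_calls,
    predict_scores,
    save_model,
    scan_entropy_threshold,
    threshold_grid,
    train_network,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_table(structure_id, aa, conserv, distance, function):
    n = len(aa)
    return pd.DataFrame(
        {
            "structure_id": structure_id,
            "resnum": np.arange(1, n + 1),
            "icode": "",
            "aa": list(aa),
            "conserv": conserv,
            "distance": distance,
            "closeness": 0.5,
            "between": 0.5,
            "pagerank": 0.5,
            "rsa": 50.0,
            "function": function,
        }
    )


class TestEncoding:
    def test_alanine_at_zero_distance(self):
        v = encode_features("A", 0.0)
        assert v.shape == (21,)
        assert v[0] == 1.0
        assert v[:20].sum() == 1.0
        assert v[20] == 0.0

    def test_indicator_always_sums_to_one(self):
        for aa in AA_ORDER:
            assert encode_features(aa, 3.0)[:20].sum() == 1.0

    def test_hand_assembled_vector(self):
        v = encode_features("H", 12.0, distance_mean=10.0, distance_std=4.0)
        expected = np.zeros(21)
        expected[AA_ORDER.index("H")] = 1.0
        expected[20] = 0.5  # (12-10)/4
        np.testing.assert_allclose(v, expected)

    def test_unknown_type_raises(self):
        with pytest.raises(ValueError, match="unknown residue type"):
            encode_features("B", 1.0)


class TestBalancedSample:
    def test_one_to_one_ratio(self):
        labels = np.r_[np.ones(3), np.zeros(100)]
        idx = balanced_sample(labels, ratio=1, seed=0)
        assert len(idx) == 6
        assert labels[idx].sum() == 3

    def test_seed_determinism(self):
        labels = np.r_[np.ones(5), np.zeros(200)]
        a = balanced_sample(labels, seed=42)
        b = balanced_sample(labels, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_insufficient_negatives_uses_all(self, caplog):
        labels = np.r_[np.ones(5), np.zeros(3)]
        with caplog.at_level("WARNING", logger="catres.net"):
            idx = balanced_sample(labels, seed=0)
        assert len(idx) == 8
        assert "negatives" in caplog.text

    def test_zero_positives_raises(self):
        with pytest.raises(ValueError):
            balanced_sample(np.zeros(10))

    def test_duplicating_negative_pool_keeps_ratio(self):
        labels = np.r_[np.ones(4), np.zeros(50)]
        doubled = np.r_[np.ones(4), np.zeros(100)]
        for lab in (labels, doubled):
            idx = balanced_sample(lab, ratio=1, seed=1)
            assert lab[idx].sum() == 4 and len(idx) == 8


class TestClassifier:
    def test_forward_pass_matches_hand_computation(self):
        clf = CatalyticNetClassifier(hidden_units=2)
        clf.W1_ = np.array([[0.3, -0.2], [0.1, 0.4]])
        clf.b1_ = np.array([0.05, -0.1])
        clf.w2_ = np.array([0.7, -0.6])
        clf.b2_ = 0.2
        clf.n_features_in_ = 2
        clf.classes_ = np.array([0, 1])
        x = np.array([[1.0, -2.0]])
        hid = _sigmoid(np.array([0.3 * 1 + 0.1 * -2 + 0.05, -0.2 * 1 + 0.4 * -2 - 0.1]))
        expected = _sigmoid(hid @ np.array([0.7, -0.6]) + 0.2)
        assert clf.decision_function(x)[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_weight_model_outputs_sigmoid_of_bias(self):
        clf = CatalyticNetClassifier(hidden_units=3)
        clf.W1_ = np.zeros((4, 3))
        clf.b1_ = np.zeros(3)
        clf.w2_ = np.zeros(3)
        clf.b2_ = -1.0
        clf.n_features_in_ = 4
        clf.classes_ = np.array([0, 1])
        out = clf.decision_function(np.random.default_rng(0).normal(size=(5, 4)))
        np.testing.assert_allclose(out, _sigmoid(-1.0))

    def test_scores_lie_in_unit_interval(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        clf = CatalyticNetClassifier(max_epochs=50, random_state=1).fit(X, y)
        s = clf.decision_function(X)
        assert np.all((s >= 0) & (s <= 1))

    def test_separable_data_reaches_perfect_training_mcc(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 0.3, size=(30, 2)), rng.normal(2, 0.3, size=(30, 2))])
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        clf = CatalyticNetClassifier(max_epochs=200, random_state=0).fit(X, y)
        mcc = matthews_cc(confusion_counts(clf.predict(X), y))
        assert mcc == pytest.approx(1.0)

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = (X.sum(axis=1) > 0).astype(int)
        a = CatalyticNetClassifier(max_epochs=30, random_state=7).fit(X, y)
        b = CatalyticNetClassifier(max_epochs=30, random_state=7).fit(X, y)
        np.testing.assert_array_equal(a.W1_, b.W1_)
        np.testing.assert_array_equal(a.w2_, b.w2_)

    def test_single_class_verification_raises(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        with pytest.raises(ValueError, match="single class"):
            CatalyticNetClassifier().fit(X, y, X_val=X[:5], y_val=np.ones(5))

    def test_sklearn_param_interface(self):
        clf = CatalyticNetClassifier(learning_rate=0.1)
        assert clf.get_params()["learning_rate"] == 0.1
        clf.set_params(max_epochs=10)
        assert clf.max_epochs == 10


class TestTrainNetwork:
    def _tables(self):
        rng = np.random.default_rng(0)
        def one(sid, seed):
            r = np.random.default_rng(seed)
            pos = make_table(sid, "H" * 20, r.uniform(3.9, 4.3, 20), r.normal(4, 0.5, 20), 1)
            neg = make_table(sid, "L" * 60, r.uniform(3.6, 4.3, 60), r.normal(15, 2, 60), 0)
            t = pd.concat([pos, neg], ignore_index=True)
            t["resnum"] = np.arange(1, len(t) + 1)
            return t
        return one("A1", 1), one("B1", 2)

    def test_selected_model_beats_final_epoch_on_verification(self):
        train, ver = self._tables()
        cfg = TrainingConfig(seed=3, max_epochs=60)
        selected = train_network(train, ver, cfg)
        # replay the identical training trajectory without epoch selection:
        # fit() consumes the rng only for init and shuffles, so omitting the
        # verification set leaves the final-epoch weights unchanged
        sample = train[train.conserv >= 3.5].pipe(self._balanced, cfg)
        X_val = encode_table(ver, selected.distance_mean, selected.distance_std)
        y_val = ver["function"].to_numpy(int)
        final_clf = CatalyticNetClassifier(
            hidden_units=cfg.hidden_units, learning_rate=cfg.learning_rate,
            max_epochs=cfg.max_epochs, random_state=cfg.seed,
        ).fit(encode_table(sample, selected.distance_mean, selected.distance_std),
              sample["function"].to_numpy(int))
        final_mcc = matthews_cc(confusion_counts(
            (final_clf.decision_function(X_val) >= 0.5).astype(int), y_val))
        assert selected.metadata["validation_mcc"] >= final_mcc - 1e-12

    @staticmethod
    def _balanced(df, cfg):
        idx = balanced_sample(df["function"].to_numpy(int), cfg.ratio, cfg.seed)
        return df.iloc[idx]

    def test_overlapping_structures_raise(self):
        train, _ = self._tables()
        with pytest.raises(ValueError, match="overlap"):
            train_network(train, train, TrainingConfig(seed=0))

    def test_reproducible_given_seed(self):
        train, ver = self._tables()
        cfg = TrainingConfig(seed=9, max_epochs=40)
        m1 = train_network(train, ver, cfg)
        m2 = train_network(train, ver, cfg)
        np.testing.assert_array_equal(m1.clf.W1_, m2.clf.W1_)
        rows = ver.head(10)
        np.testing.assert_array_equal(predict_scores(m1, rows), predict_scores(m2, rows))

    def test_model_roundtrip_through_text_file(self, tmp_path):
        train, ver = self._tables()
        model = train_network(train, ver, TrainingConfig(seed=1, max_epochs=40))
        path = tmp_path / "model.txt"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.clf.W1_, model.clf.W1_)
        assert loaded.distance_mean == model.distance_mean
        np.testing.assert_array_equal(
            predict_scores(loaded, ver), predict_scores(model, ver)
        )


class TestThresholdScan:
    def test_grid_has_sixteen_thresholds(self):
        grid = threshold_grid(2.5, 4.0, 0.1)
        assert len(grid) == 16
        np.testing.assert_allclose(grid[0], 2.5)
        np.testing.assert_allclose(grid[-1], 4.0)

    def test_step_larger_than_range_gives_single_threshold(self):
        grid = threshold_grid(2.5, 2.55, 0.2)
        np.testing.assert_allclose(grid, [2.5])

    def test_recovers_planted_optimum(self):
        train, ver, scan = planted_scan_tables(seed=17)
        model = train_network(train, ver, TrainingConfig(seed=17, max_epochs=200))
        best, table = scan_entropy_threshold(scan, model, 2.5, 4.0, 0.1)
        assert len(table) == 16
        assert best == pytest.approx(3.9)
        # MCC at the planted threshold dominates the rest of the grid
        mccs = table.set_index("threshold")["mcc"]
        assert mccs.loc[3.9] == mccs.max()

    def test_prefiltered_positives_count_as_false_negatives(self):
        table = make_table("X", "HHHH", [4.0, 4.0, 1.0, 1.0], [4.0, 4.0, 4.0, 4.0],
                           [1, 1, 1, 0])
        clf = CatalyticNetClassifier()
        clf.W1_ = np.zeros((21, 10)); clf.b1_ = np.zeros(10)
        clf.w2_ = np.zeros(10); clf.b2_ = 10.0  # always-positive network
        clf.n_features_in_ = 21; clf.classes_ = np.array([0, 1])
        from catres.net import NetworkModel
        model = NetworkModel(clf, 0.0, 1.0)
        calls = predict_calls(model, table, conservation_threshold=3.8)
        np.testing.assert_array_equal(calls, [1, 1, 0, 0])
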