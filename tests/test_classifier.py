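"""The dense-network discriminator, the seven metrics, and the
cross-validation / versatility harnesses."""

import numpy as np
import pytest

from premir.classifier import (
    DenseHairpinClassifier,
    ModelSpec,
    compute_metrics,
    kfold_cv,
    leave_one_group_out,
    paired_folds,
    predict_proba,
    train,
)
from premir.simulate import make_feature_table

FAST = ModelSpec(epochs=40)


def _table(n=400, sep=6.0, noise=0.0, seed=0):
    df = make_feature_table(n, class_sep=sep, noise=noise, seed=seed)
    return df.drop(columns="label").values, df["label"].values


class TestTrain:
    def test_separable_data_fits_to_high_accuracy(self):
        X, y = _table(1000, sep=6.0)
        model = train(X, y, FAST, seed=1)
        acc = compute_metrics(y, predict_proba(model, X)).accuracy
        assert acc >= 0.99

    def test_same_seed_identical_predictions(self):
        X, y = _table(200)
        a = predict_proba(train(X, y, FAST, seed=5), X)
        b = predict_proba(train(X, y, FAST, seed=5), X)
        assert np.array_equal(a, b)

    def test_single_class_labels_rejected(self):
        X, _ = _table(50)
        with pytest.raises(ValueError):
            train(X, np.ones(len(X)), FAST, seed=0)

    def test_sklearn_estimator_interface(self):
        est = DenseHairpinClassifier(epochs=5)
        params = est.get_params()
        assert "hidden_layers" in params and "random_state" in params
        est.set_params(epochs=7)
        assert est.epochs == 7
        X, y = _table(60)
        est.fit(X, y)
        assert hasattr(est, "classes_") and est.n_features_in_ == X.shape[1]
        assert set(est.predict(X)) <= set(est.classes_)

    def test_seven_hidden_layers_by_default(self):
        assert len(ModelSpec().hidden_layers) == 7


class TestPredictProba:
    def test_probabilities_valid_and_sum_to_one(self):
        X, y = _table(200)
        model = train(X, y, FAST, seed=2)
        proba = model.predict_proba(X)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_deep_positive_point_scores_high(self):
        X, y = _table(1000, sep=8.0)
        model = train(X, y, FAST, seed=2)
        deep = X[y == 1].mean(axis=0, keepdims=True)
        assert predict_proba(model, deep)[0] > 0.9

    def test_empty_input_gives_empty_output(self):
        X, y = _table(60)
        model = train(X, y, FAST, seed=2)
        assert model.predict_proba(np.zeros((0, X.shape[1]))).shape == (0, 2)

    def test_width_mismatch_rejected(self):
        X, y = _table(60)
        model = train(X, y, FAST, seed=2)
        with pytest.raises(ValueError):
            model.predict_proba(X[:, :50])


class TestComputeMetrics:
    def test_perfect_scores(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([1.0, 0.9, 0.1, 0.0])
        rep = compute_metrics(y, s)
        for m in ("accuracy", "sensitivity", "specificity", "precision", "f1", "mcc", "auc"):
            assert getattr(rep, m) == pytest.approx(1.0)

    def test_textbook_confusion_matrix(self):
        # TP=40, TN=45, FP=5, FN=10
        y = np.array([1] * 50 + [0] * 50)
        s = np.array([0.9] * 40 + [0.1] * 10 + [0.9] * 5 + [0.1] * 45)
        rep = compute_metrics(y, s)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.9)
        assert rep.precision == pytest.approx(0.888888, abs=1e-4)
        assert rep.f1 == pytest.approx(0.842105, abs=1e-4)
        assert rep.mcc == pytest.approx(0.703526, abs=1e-4)

    def test_auc_one_when_positives_outrank(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        s = np.concatenate([rng.uniform(0, 0.4, 30), rng.uniform(0.6, 1.0, 30)])
        assert compute_metrics(y, s).auc == pytest.approx(1.0)

    def test_single_class_gives_nan_with_warning(self):
        with pytest.warns(UserWarning):
            rep = compute_metrics(np.ones(10), np.linspace(0, 1, 10))
        assert np.isnan(rep.auc) and np.isnan(rep.mcc)

    def test_brute_force_recount_on_1000_random_draws(self, rng):
        """Metrics match an explicit confusion-matrix recount and AUC matches
        pairwise comparison counting (ties count half)."""
        from sklearn.metrics import roc_auc_score

        for _ in range(1000):
            n = int(rng.integers(8, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # rounding induces ties
            rep = compute_metrics(y, s)
            pred = (s >= 0.5).astype(int)
            tp = np.sum((pred == 1) & (y == 1))
            tn = np.sum((pred == 0) & (y == 0))
            assert rep.accuracy == pytest.approx((tp + tn) / n)
            pos = s[y == 1]
            neg = s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            pair_auc = wins / (len(pos) * len(neg))
            assert rep.auc == pytest.approx(pair_auc)
            assert rep.auc == pytest.approx(roc_auc_score(y, s))


class TestKFoldCV:
    def test_folds_partition_and_pair_classes(self, rng):
        y = np.array([1] * 57 + [0] * 43)
        folds = paired_folds(y, 10, seed=3)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(100))
        for f in folds:
            assert y[f].sum() in (5, 6)  # positives spread evenly

    def test_fold_assignment_deterministic(self):
        y = np.array([1, 0] * 30)
        a = paired_folds(y, 5, seed=9)
        b = paired_folds(y, 5, seed=9)
        assert all(np.array_equal(x, z) for x, z in zip(a, b))

    def test_k_exceeding_class_size_rejected(self):
        y = np.array([1] * 3 + [0] * 50)
        with pytest.raises(ValueError):
            paired_folds(y, 10, seed=0)

    def test_separable_dataset_cross_validates_well(self):
        X, y = _table(300, sep=6.0, seed=4)
        rep = kfold_cv(X, y, k=5, spec=FAST, seed=4)
        assert rep.accuracy >= 0.95
        assert rep.per_fold is not None and len(rep.per_fold) == 5
        assert rep.std is not None


class TestLeaveOneGroupOut:
    def _groups(self, n=120, k=3):
        groups = {}
        for g in range(k):
            df = make_feature_table(
                n, class_sep=6.0, seed=50 + g, direction_seed=777
            )
            groups[f"species_{g}"] = (
                df.drop(columns="label").values,
                df["label"].values,
            )
        return groups

    def test_shared_generative_model_generalizes(self):
        out = leave_one_group_out(self._groups(), spec=FAST, seed=6)
        assert len(out) == 3
        for rep in out.values():
            assert rep.accuracy >= 0.9

    def test_held_out_group_never_in_training(self, monkeypatch):
        """Structural leakage check: the training matrix passed to the
        fitting routine never contains a row of the held-out group."""
        groups = self._groups(n=40)
        seen = {}
        import premir.classifier as mod

        real_train = mod.train

        def spy(features, labels, spec=None, seed=0):
            seen[seed] = np.asarray(features).copy()
            return real_train(features, labels, spec, seed)

        monkeypatch.setattr(mod, "train", spy)
        mod.leave_one_group_out(groups, spec=FAST, seed=100)
        for gi, name in enumerate(sorted(groups)):
            X_held = groups[name][0]
            X_train = seen[100 + gi]
            held_rows = {tuple(np.round(r, 6)) for r in X_held}
            train_rows = {tuple(np.round(r, 6)) for r in X_train}
            assert not held_rows & train_rows

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            leave_one_group_out({"only": _table(40)}, spec=FAST)


class TestNoiseSanity:
    def test_test_accuracy_tracks_label_noise(self):
        """With label-noise rate eps, held-out accuracy approaches 1 - eps."""
        rng = np.random.default_rng(0)
        for eps in (0.0, 0.1, 0.2):
            df = make_feature_table(600, class_sep=8.0, noise=eps, seed=int(eps * 100))
            order = rng.permutation(len(df))
            X = df.drop(columns="label").values[order]
            y = df["label"].values[order]
            model = train(X[:800], y[:800], FAST, seed=8)
            acc = compute_metrics(y[800:], predict_proba(model, X[800:])).accuracy
            assert abs(acc - (1 - eps)) <= 0.06
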