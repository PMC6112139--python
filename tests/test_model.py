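import random

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from _oracles import mcc_via_pearson, mutual_information_brute
from mirquant.model import (
    LabeledDataset,
    ModelConfig,
    ModelError,
    TrainedModel,
    forward_select,
    mcc,
    mrmr_rank,
    predict,
    quality_score,
    train,
)

FAST = ModelConfig(split_replicates=5, cv_folds=5, seed=0)


def blobs(n=120, n_features=5, informative=2, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, n_features))
    for k in range(informative):
        X[:, k] += y * sep
    frame = pd.DataFrame(X, columns=[f"f{k}" for k in range(n_features)])
    return LabeledDataset(frame, y)


class TestMcc:
    def test_perfect(self):
        assert mcc(10, 0, 10, 0) == 1.0

    def test_chance(self):
        assert mcc(5, 5, 5, 5) == 0.0

    def test_zero_denominator_convention(self):
        assert mcc(0, 0, 10, 0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ModelError):
            mcc(-1, 0, 0, 0)

    def test_formula_value(self):
        value = mcc(90, 20, 80, 10)
        assert value == pytest.approx(mcc_via_pearson(90, 20, 80, 10), abs=1e-12)

    def test_equals_pearson_on_random_matrices(self):
        rng = random.Random(7)
        for _ in range(100):
            tp, fp, tn, fn = (rng.randint(0, 50) for _ in range(4))
            if tp + fp + tn + fn == 0:
                continue
            assert mcc(tp, fp, tn, fn) == pytest.approx(
                mcc_via_pearson(tp, fp, tn, fn), abs=1e-12
            )


class TestMrmr:
    def toy(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        frame = pd.DataFrame(
            {
                "label_copy": y.astype(float),
                "informative": y + rng.normal(scale=0.8, size=n),
                "noise": rng.normal(size=n),
                "constant": np.ones(n),
            }
        )
        return LabeledDataset(frame, y)

    def test_label_copy_ranked_first(self):
        ranked = mrmr_rank(self.toy())
        assert ranked[0][0] == "label_copy"

    def test_duplicate_feature_demoted(self):
        ds = self.toy()
        ds.features["label_copy2"] = ds.features["label_copy"]
        ranked = [name for name, _ in mrmr_rank(ds)]
        # the duplicate is fully redundant: it must not follow its twin directly
        assert ranked[0] in ("label_copy", "label_copy2")
        assert ranked[1] not in ("label_copy", "label_copy2")

    def test_constant_feature_zero_relevance(self):
        ranked = dict(mrmr_rank(self.toy()))
        assert ranked["constant"] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_mi_agreement(self):
        # 3-feature toy table: first pick maximizes MI with the label
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 150)
        ds = LabeledDataset(
            pd.DataFrame(
                {
                    "label_copy": y.astype(float),
                    "noise1": rng.normal(size=150),
                    "noise2": rng.normal(size=150),
                }
            ),
            y,
        )
        from mirquant.model import _discretize

        binned = {
            name: list(_discretize(ds.features[name].to_numpy(float), 10))
            for name in ds.feature_names
        }
        relevances = {
            name: mutual_information_brute(binned[name], list(ds.labels))
            for name in ds.feature_names
        }
        ranked = mrmr_rank(ds)
        assert ranked[0][0] == max(relevances, key=relevances.get)
        assert ranked[0][1] == pytest.approx(relevances[ranked[0][0]], rel=1e-6)
        # second pick maximizes relevance minus redundancy vs the first
        first = ranked[0][0]
        scores = {
            name: relevances[name]
            - mutual_information_brute(binned[name], binned[first])
            for name in ds.feature_names
            if name != first
        }
        assert ranked[1][0] == max(scores, key=scores.get)
        assert ranked[1][1] == pytest.approx(scores[ranked[1][0]], rel=1e-6)

    def test_single_feature_rejected(self):
        ds = LabeledDataset(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0, 1]))
        with pytest.raises(ModelError):
            mrmr_rank(ds)


class TestForwardSelect:
    def test_recovers_small_k_on_informative_features(self):
        ds = blobs(n=200, n_features=10, informative=3)
        ranked = [name for name, _ in mrmr_rank(ds)]
        k, selected, report = forward_select(ds, ranked, FAST)
        assert k <= 5
        assert selected == ranked[:k]

    def test_epsilon_zero_is_argmax(self):
        ds = blobs(n=150, n_features=6, informative=2, seed=2)
        ranked = [name for name, _ in mrmr_rank(ds)]
        config = ModelConfig(split_replicates=5, selection_epsilon=0.0, seed=1)
        k, _, report = forward_select(ds, ranked, config)
        assert report.loc[report["k"] == k, "mean_mcc"].iloc[0] == report["mean_mcc"].max()

    def test_pure_noise_returns_smallest_k(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        ds = LabeledDataset(frame, rng.integers(0, 2, 80))
        ranked = [name for name, _ in mrmr_rank(ds)]
        k, _, report = forward_select(ds, ranked, FAST)
        assert abs(report["mean_mcc"]).max() < 0.45  # no real signal
        # with everything within epsilon of the max, the smallest qualifying k wins
        best = report["mean_mcc"].max()
        expected = int(report.loc[report["mean_mcc"] >= best - FAST.selection_epsilon, "k"].iloc[0])
        assert k == expected

    def test_k_non_increasing_in_epsilon(self):
        ds = blobs(n=160, n_features=8, informative=2, seed=4)
        ranked = [name for name, _ in mrmr_rank(ds)]
        ks = []
        for eps in (0.0, 0.01, 0.05, 0.2):
            config = ModelConfig(split_replicates=5, selection_epsilon=eps, seed=3)
            k, _, _ = forward_select(ds, ranked, config)
            ks.append(k)
        assert ks == sorted(ks, reverse=True)


class TestTrain:
    def test_separable_blobs_perfect_heldout(self):
        ds = blobs(n=160, informative=3, sep=6.0, seed=6)
        train_idx = np.arange(0, 120)
        test_idx = np.arange(120, 160)
        dtr = LabeledDataset(
            ds.features.iloc[train_idx].reset_index(drop=True), ds.labels[train_idx]
        )
        model = train(dtr, dtr.feature_names, FAST)
        decisions = predict(model, ds.features.iloc[test_idx].to_dict("records"))
        got = [label for _, label in decisions]
        assert matthews_corrcoef(ds.labels[test_idx], got) == 1.0

    def test_best_params_in_grid(self):
        ds = blobs(n=100, seed=8)
        model = train(ds, ds.feature_names, FAST)
        assert model.C in FAST.c_grid
        assert model.gamma in FAST.gamma_grid

    def test_standardization_stats(self):
        ds = blobs(n=100, seed=9)
        model = train(ds, ds.feature_names, FAST)
        X = ds.features.to_numpy(dtype=float)
        Z = (X - model.means) / model.scales
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(Z.var(axis=0) - 1) < 1e-9)

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(ModelError):
            train(LabeledDataset(frame, np.zeros(3, dtype=int)), ["a", "b"], FAST)

    def test_permuted_labels_near_zero_mcc(self):
        ds = blobs(n=100, informative=2, seed=10)
        rng = np.random.default_rng(0)
        mccs = []
        for rep in range(8):
            y_perm = rng.permutation(ds.labels)
            dtr = LabeledDataset(ds.features.iloc[:70].reset_index(drop=True), y_perm[:70])
            if len(set(dtr.labels)) < 2:
                continue
            model = train(dtr, dtr.feature_names, ModelConfig(cv_folds=5, seed=rep))
            decisions = predict(model, ds.features.iloc[70:].to_dict("records"))
            mccs.append(
                matthews_corrcoef(y_perm[70:], [label for _, label in decisions])
            )
        assert abs(np.mean(mccs)) < 0.25

    def test_json_round_trip(self, tmp_path):
        ds = blobs(n=80, seed=11)
        model = train(ds, ds.feature_names, FAST)
        path = tmp_path / "model.json"
        model.to_json(path)
        again = TrainedModel.from_json(path)
        X = ds.features.to_numpy(dtype=float)
        np.testing.assert_allclose(
            model.decision_function(X), again.decision_function(X), rtol=1e-12
        )


class TestPredict:
    def model(self):
        ds = blobs(n=80, seed=12)
        return train(ds, ds.feature_names, FAST), ds

    def test_training_positive_repredicted(self):
        model, ds = self.model()
        positives = ds.features[ds.labels == 1].to_dict("records")
        decisions = predict(model, positives[:5])
        assert all(label == 1 for _, label in decisions)

    def test_deterministic(self):
        model, ds = self.model()
        vec = ds.features.iloc[:3].to_dict("records")
        assert predict(model, vec) == predict(model, vec)

    def test_unknown_feature_error(self):
        model, _ = self.model()
        with pytest.raises(ModelError, match="mystery"):
            predict(model, [{"mystery": 1.0}])

    def test_missing_selected_imputed_zero(self):
        model, ds = self.model()
        full = ds.features.iloc[0].to_dict()
        sparse = {k: v for k, v in full.items() if k != "f4"}
        full_zero = dict(full, f4=0.0)
        assert predict(model, [sparse]) == predict(model, [full_zero])

    def test_empty_input(self):
        model, _ = self.model()
        assert predict(model, []) == []


class TestQualityScore:
    def test_best_of_100(self):
        values = list(range(100, 0, -1))
        scores = quality_score(values)
        assert scores[0] == pytest.approx(0.99)

    def test_worst_is_zero(self):
        scores = quality_score([3.0, 2.0, 1.0])
        assert scores[-1] == 0.0

    def test_ties_share_mean_rank(self):
        scores = quality_score([5.0, 5.0, 1.0])
        assert scores[0] == scores[1]
        assert scores[0] == pytest.approx(1 - 1.5 / 3)
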