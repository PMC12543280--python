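"""Classifier protocol: weighting, splitting, training, CV, search, confusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import smstoich as sm
from smstoich.cnn import LabeledDataset, default_search_grid

FAST_ARCH_4 = sm.ArchitectureSpec(conv_blocks=((7, 6),), dense=(16,), n_classes=4, head_bins=16)
FAST_ARCH_2 = sm.ArchitectureSpec(conv_blocks=((7, 6),), dense=(16,), n_classes=2, head_bins=16)


def synthetic_dataset(n, frames, channel="farred", noise=0.1, seed=0):
    """Separable staircase dataset: class = number of unit drops (0 -> rejected)."""
    rng = np.random.default_rng(seed)
    names = ("rejected", "1-step", "2-step", "3plus") if channel == "farred" else ("rejected", "1-step")
    K = 4 if channel == "farred" else 2
    X = np.empty((n, frames), dtype=np.float32)
    y = rng.integers(0, K, size=n)
    for i in range(n):
        k = y[i]
        x = np.zeros(frames)
        if k:
            drops = np.sort(rng.choice(np.arange(10, frames - 10), size=k, replace=False))
            for d in drops:
                x[d:] -= 1.0
        x += rng.normal(0, noise, size=frames)
        sd = x.std()
        X[i] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return LabeledDataset(X, y, names, channel)


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        assert np.allclose(sm.compute_class_weights([10, 10]), [1.0, 1.0])

    def test_reference_corpus_weights(self):
        w = sm.compute_class_weights([12563, 10926, 5053, 1593])
        assert np.allclose(np.round(w, 3), [0.600, 0.690, 1.491, 4.729])
        assert np.argmax(w) == 3  # rarest class gets the largest weight

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            sm.compute_class_weights([5, 0, 3])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=10**6), min_size=2, max_size=6))
    def test_weight_identity(self, counts):
        """sum_c w_c * n_c = N for every count vector."""
        counts = np.array(counts, dtype=float)
        w = sm.compute_class_weights(counts)
        assert np.isclose((w * counts).sum(), counts.sum(), rtol=1e-12)


class TestStratifiedSplit:
    def test_balanced_two_class_split(self):
        ds = synthetic_dataset(100, 32, channel="green", seed=1)
        ds.y = np.repeat([0, 1], 50)
        tr, va = sm.stratified_split(ds, 0.8, seed=0)
        assert tr.class_counts() == {"rejected": 40, "1-step": 40}
        assert va.class_counts() == {"rejected": 10, "1-step": 10}

    def test_four_class_proportions(self):
        ds = synthetic_dataset(100, 32, seed=2)
        ds.y = np.repeat([0, 1, 2, 3], [40, 30, 20, 10])
        tr, _ = sm.stratified_split(ds, 0.8, seed=0)
        assert list(np.bincount(tr.y)) == [32, 24, 16, 8]

    def test_same_seed_reproducible_and_disjoint(self):
        ds = synthetic_dataset(80, 32, seed=3)
        a = sm.stratified_split(ds, 0.8, seed=5)
        b = sm.stratified_split(ds, 0.8, seed=5)
        assert np.array_equal(a[0].X, b[0].X) and np.array_equal(a[1].y, b[1].y)
        assert len(a[0]) + len(a[1]) == len(ds)

    def test_tiny_class_rejected(self):
        ds = synthetic_dataset(10, 32, channel="green", seed=4)
        ds.y = np.array([0] * 9 + [1])
        with pytest.raises(ValueError):
            sm.stratified_split(ds, 0.8, seed=0)


class TestTrainAndClassify:
    def test_single_epoch_smoke_emits_metrics(self):
        ds = synthetic_dataset(120, 64, seed=5)
        tr, va = sm.stratified_split(ds, 0.8, seed=0)
        model, m = sm.train(tr, va, FAST_ARCH_4, sm.TrainingConfig(epochs=1, seed=0))
        assert 0.0 <= m["accuracy"] <= 1.0 and len(m["per_class_f1"]) == 4

    def test_separable_two_class_learned(self):
        ds = synthetic_dataset(400, 128, channel="green", seed=6)
        tr, va = sm.stratified_split(ds, 0.8, seed=0)
        model, m = sm.train(
            tr, va, FAST_ARCH_2, sm.TrainingConfig(epochs=15, batch_size=32, seed=0)
        )
        assert m["accuracy"] >= 0.97

    def test_probabilities_sum_to_one_and_inference_deterministic(self):
        ds = synthetic_dataset(60, 64, seed=7)
        model, _ = sm.train(ds, None, FAST_ARCH_4, sm.TrainingConfig(epochs=1, seed=0))
        labels1, probs1 = sm.classify(model, ds.X)
        labels2, probs2 = sm.classify(model, ds.X)
        assert np.allclose(probs1.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(labels1, labels2) and np.array_equal(probs1, probs2)
        assert set(labels1) <= set(ds.class_names)

    def test_wrong_input_length_rejected(self):
        ds = synthetic_dataset(60, 64, seed=8)
        model, _ = sm.train(ds, None, FAST_ARCH_4, sm.TrainingConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            sm.classify(model, np.zeros((3, 100), dtype=np.float32))

    def test_same_seed_same_model(self):
        ds = synthetic_dataset(100, 64, seed=9)
        m1, _ = sm.train(ds, None, FAST_ARCH_4, sm.TrainingConfig(epochs=2, seed=3))
        m2, _ = sm.train(ds, None, FAST_ARCH_4, sm.TrainingConfig(epochs=2, seed=3))
        for k in m1.net.params:
            assert np.array_equal(m1.net.params[k], m2.net.params[k])

    def test_save_load_round_trip(self, tmp_path):
        ds = synthetic_dataset(60, 64, seed=10)
        model, _ = sm.train(ds, None, FAST_ARCH_4, sm.TrainingConfig(epochs=1, seed=0))
        model.save(tmp_path / "model")
        loaded = sm.TrainedClassifier.load(tmp_path / "model")
        assert np.allclose(model.predict_proba(ds.X), loaded.predict_proba(ds.X))

    def test_weighting_helps_minority_recall(self):
        """Paired over 5 seeds: ICF-weighted minority recall >= unweighted."""
        weighted_total = unweighted_total = 0.0
        for seed in range(5):
            ds = synthetic_dataset(400, 96, channel="green", noise=0.6, seed=20 + seed)
            ds.y = (np.arange(400) % 10 == 0).astype(int)  # 10% minority
            ds = ds.subset(np.random.default_rng(seed).permutation(400))
            tr, va = sm.stratified_split(ds, 0.8, seed=seed)
            counts = np.bincount(tr.y, minlength=2)
            for weights, bucket in ((sm.compute_class_weights(counts), "w"), (np.ones(2), "u")):
                cfg = sm.TrainingConfig(epochs=4, seed=seed, class_weights=weights)
                model, _ = sm.train(tr, va, FAST_ARCH_2, cfg)
                labels, _ = sm.classify(model, va.X)
                minority = va.y == 1
                recall = (labels[minority] == "1-step").mean() if minority.any() else 0.0
                if bucket == "w":
                    weighted_total += recall
                else:
                    unweighted_total += recall
        assert weighted_total >= unweighted_total - 1e-9


class TestCrossValidate:
    def test_five_folds_and_mean_is_arithmetic(self):
        ds = synthetic_dataset(300, 64, seed=11)
        cv = sm.cross_validate(ds, FAST_ARCH_4, sm.TrainingConfig(epochs=1, seed=0), k=5)
        assert len(cv["folds"]) == 5
        accs = [m["accuracy"] for m in cv["folds"]]
        assert cv["mean_accuracy"] == pytest.approx(np.mean(accs))

    def test_k_exceeding_class_count_rejected(self):
        ds = synthetic_dataset(40, 64, seed=12)
        ds.y = np.array([0] * 37 + [1, 2, 3])
        with pytest.raises(ValueError):
            sm.cross_validate(ds, FAST_ARCH_4, sm.TrainingConfig(epochs=1), k=5)

    def test_fold_metrics_invariant_to_row_order(self):
        ds = synthetic_dataset(200, 64, seed=13)
        cfg = sm.TrainingConfig(epochs=1, seed=0)
        cv1 = sm.cross_validate(ds, FAST_ARCH_4, cfg, k=4)
        perm = np.random.default_rng(0).permutation(len(ds))
        cv2 = sm.cross_validate(ds.subset(perm), FAST_ARCH_4, cfg, k=4)
        assert cv1["mean_accuracy"] == pytest.approx(cv2["mean_accuracy"], abs=0.05)


class TestSearch:
    def test_degenerate_candidate_ranks_last(self):
        ds = synthetic_dataset(200, 64, seed=14)
        dead = sm.ArchitectureSpec(conv_blocks=((7, 6),), dense=(0,), n_classes=4, head_bins=16)
        cfg = sm.TrainingConfig(epochs=6, batch_size=32)
        res = sm.search(ds, [(FAST_ARCH_4, cfg), (dead, cfg)], seed=0, top_k=1, cv_folds=2)
        assert res["leaderboard"][0]["arch"] is FAST_ARCH_4
        assert len(res["leaderboard"]) == 2

    def test_search_deterministic(self):
        ds = synthetic_dataset(150, 64, seed=15)
        cands = [
            (FAST_ARCH_4, sm.TrainingConfig(epochs=1)),
            (sm.ArchitectureSpec(conv_blocks=((5, 4),), dense=(8,), n_classes=4, head_bins=16),
             sm.TrainingConfig(epochs=1)),
        ]
        r1 = sm.search(ds, cands, seed=1, top_k=2, cv_folds=2)
        r2 = sm.search(ds, cands, seed=1, top_k=2, cv_folds=2)
        assert [x["candidate"] for x in r1["leaderboard"]] == [x["candidate"] for x in r2["leaderboard"]]
        assert [x["val_accuracy"] for x in r1["leaderboard"]] == [x["val_accuracy"] for x in r2["leaderboard"]]
        assert r1["best"]["candidate"] == r2["best"]["candidate"]

    def test_empty_candidate_list_rejected(self):
        ds = synthetic_dataset(50, 64, seed=16)
        with pytest.raises(ValueError):
            sm.search(ds, [])

    def test_default_grid_size(self):
        assert len(default_search_grid(4)) == 12


class TestConfusionMatrix:
    def test_perfect_predictions_give_identity(self):
        names = ("rejected", "1-step")
        raw, norm = sm.confusion_matrix(["rejected", "1-step"], ["rejected", "1-step"], names)
        assert np.array_equal(norm, np.eye(2))
        assert raw.sum() == 2

    def test_raw_rows_sum_to_truth_counts(self, rng):
        names = ("rejected", "1-step", "2-step", "3plus")
        t = rng.integers(0, 4, size=500)
        p = rng.integers(0, 4, size=500)
        raw, norm = sm.confusion_matrix(t, p, names)
        assert np.array_equal(raw.sum(axis=1), np.bincount(t, minlength=4))
        present = np.bincount(t, minlength=4) > 0
        assert np.allclose(norm[present].sum(axis=1), 1.0)

    def test_random_predictions_near_uniform(self, rng):
        names = ("a", "b", "c", "d")
        t = rng.integers(0, 4, size=4000)
        p = rng.integers(0, 4, size=4000)
        _, norm = sm.confusion_matrix(t, p, names)
        assert np.allclose(norm, 0.25, atol=0.05)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            sm.confusion_matrix(["x"], ["rejected"], ("rejected", "1-step"))

    def test_absent_class_row_is_zero(self):
        names = ("rejected", "1-step")
        _, norm = sm.confusion_matrix(["rejected"], ["rejected"], names)
        assert np.array_equal(norm[1], [0.0, 0.0])
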