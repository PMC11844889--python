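"""Dataset construction, CNN architecture, training protocol, and SVM."""

import numpy as np
import pytest

from spontlfp import nn
from spontlfp.decoding import (CNNSpec, TrainConfig, build_cnn, build_dataset,
                               DecodingError, evaluate_model,
                               evaluate_repetitions, make_svm_factory,
                               session_spectrograms, train_classifier,
                               train_svm, ClassifierResult)


def toy_items(n_air, n_touch, rng, shape=(6, 6), shift=0.0):
    """Noisy images whose mean differs between classes by ``shift``."""
    items = []
    for _ in range(n_air):
        items.append((rng.standard_normal(shape), "airflow"))
    for _ in range(n_touch):
        items.append((rng.standard_normal(shape) + shift, "touch"))
    return items


class TestBuildDataset:
    def test_minority_bootstrapped_to_majority(self, rng):
        ds = build_dataset(toy_items(110, 100, rng), rng)
        assert ds.images.shape[0] == 220
        assert (ds.labels == 0).sum() == (ds.labels == 1).sum() == 110

    def test_80_10_10_split_with_equal_classes(self, rng):
        ds = build_dataset(toy_items(100, 100, rng), rng)
        assert (ds.idx_train.size, ds.idx_val.size, ds.idx_test.size) == (160, 20, 20)
        for split in ("train", "val", "test"):
            y = ds.y(split)
            assert (y == 0).sum() == (y == 1).sum()

    def test_splits_disjoint_and_exhaustive(self, rng):
        ds = build_dataset(toy_items(60, 50, rng), rng)
        allidx = np.concatenate([ds.idx_train, ds.idx_val, ds.idx_test])
        assert np.array_equal(np.sort(allidx), np.arange(ds.images.shape[0]))

    def test_scaler_fit_on_train_only(self, rng):
        ds = build_dataset(toy_items(50, 50, rng), rng)
        Xtr = ds.X_flat("train")
        assert np.allclose(Xtr.min(axis=0), 0.0)
        assert np.allclose(Xtr.max(axis=0), 1.0)
        Xte = ds.X_flat("test")
        assert Xte.min() < 0 or Xte.max() > 1   # test values may escape [0,1]

    def test_missing_label_rejected(self, rng):
        with pytest.raises(DecodingError, match="absent"):
            build_dataset(toy_items(10, 0, rng), rng)

    def test_label_shuffle_preserves_counts_and_test_labels(self, rng):
        ds = build_dataset(toy_items(50, 50, rng), rng)
        sh = ds.shuffled_labels(rng)
        for split in ("train", "val"):
            assert (sh.y(split) == 1).sum() == (ds.y(split) == 1).sum()
        assert np.array_equal(sh.y("test"), ds.y("test"))


class TestBuildCNN:
    def test_layer_shapes_for_50x500_input(self):
        """Shape-arithmetic oracle: two valid 3x3 stride-1 convolutions
        then a 2x2 stride-1 pool."""
        model = build_cnn((50, 500), rng=0)
        assert model.layer_shapes["conv1"] == (48, 498, 24)
        assert model.layer_shapes["conv2"] == (46, 496, 48)
        assert model.layer_shapes["pool"] == (45, 495, 48)

    def test_output_width_two_and_map_counts(self, rng):
        model = build_cnn((12, 10), rng=rng)
        x = rng.random((3, 1, 12, 10)).astype(np.float32)
        assert model.forward(x).shape == (3, 2)
        convs = [l for l in model.layers if isinstance(l, nn.Conv2d)]
        assert [c.out_channels for c in convs] == [24, 48]

    def test_too_small_input_rejected(self):
        with pytest.raises(DecodingError, match="too small"):
            build_cnn((5, 5), rng=0)

    def test_conventional_pool_stride_option(self):
        model = build_cnn((20, 20), CNNSpec(pool_stride=2), rng=0)
        assert model.layer_shapes["pool"] == (8, 8, 48)


def tiny_cfg(epochs=12):
    return TrainConfig(batch_size=10, epochs=epochs)


class TestTraining:
    def test_separable_constants_reach_perfect_accuracy(self, rng):
        items = [(np.zeros((8, 8)), "airflow") for _ in range(30)]
        items += [(np.ones((8, 8)), "touch") for _ in range(30)]
        ds = build_dataset(items, rng)
        model = build_cnn((8, 8), CNNSpec(dropout=0.2), rng)
        model, hist = train_classifier(model, ds, tiny_cfg(), rng)
        acc, auroc = evaluate_model(model, ds)
        assert acc == 1.0 and auroc == 1.0
        assert len(hist["val_loss"]) == 12

    def test_random_labels_stay_near_chance(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds = build_dataset(toy_items(30, 30, rng, shift=0.0), rng)
            model = build_cnn((6, 6), rng=rng)
            model, _ = train_classifier(model, ds, tiny_cfg(6), rng)
            accs.append(evaluate_model(model, ds)[0])
        # no information: mean accuracy within the binomial null band
        se = 0.5 / np.sqrt(10 * 6)
        assert abs(np.mean(accs) - 0.5) < 3 * se

    def test_accuracy_non_decreasing_in_epochs_on_average(self):
        means = []
        for epochs in (1, 15):
            accs = []
            for seed in range(10):
                rng = np.random.default_rng(100 + seed)
                ds = build_dataset(toy_items(40, 40, rng, shift=0.8), rng)
                model = build_cnn((6, 6), rng=rng)
                model, _ = train_classifier(model, ds, tiny_cfg(epochs), rng)
                accs.append(evaluate_model(model, ds)[0])
            means.append(np.mean(accs))
        assert means[1] >= means[0]

    def test_model_selection_restores_best_validation_snapshot(self, rng):
        ds = build_dataset(toy_items(40, 40, rng, shift=0.5), rng)
        model = build_cnn((6, 6), rng=rng)
        model, hist = train_classifier(model, ds, tiny_cfg(), rng)
        from spontlfp.decoding import _epoch_loss

        val = _epoch_loss(model, ds.X_images("val"), ds.y("val"))
        assert val == pytest.approx(min(hist["val_loss"]), rel=1e-5)

    def test_no_information_leak_from_test_labels(self, rng):
        """Permuting test labels leaves the trained parameters identical."""
        items = toy_items(30, 30, rng, shift=0.5)
        ds = build_dataset(items, np.random.default_rng(5))
        ds_perm = build_dataset(items, np.random.default_rng(5))
        ds_perm.labels = ds_perm.labels.copy()
        ds_perm.labels[ds_perm.idx_test] = np.random.default_rng(9).permutation(
            ds_perm.labels[ds_perm.idx_test])
        hashes = []
        for d in (ds, ds_perm):
            model = build_cnn((6, 6), rng=np.random.default_rng(7))
            model, _ = train_classifier(model, d, tiny_cfg(4),
                                        np.random.default_rng(7))
            hashes.append(model.state_hash())
        assert hashes[0] == hashes[1]


class TestSVM:
    def test_xor_needs_nonlinear_kernel(self):
        rng = np.random.default_rng(0)
        n = 400
        pts = rng.uniform(-1, 1, (n, 2))
        labels = ["touch" if (p[0] > 0) != (p[1] > 0) else "airflow" for p in pts]
        items = [(p.reshape(1, 2), lb) for p, lb in zip(pts, labels)]
        ds = build_dataset(items, rng)
        _, acc_rbf, _ = train_svm(ds, kernel="rbf")
        _, acc_lin, _ = train_svm(ds, kernel="linear")
        assert acc_rbf >= 0.9
        assert acc_lin <= 0.75

    def test_separable_duplicates_perfect(self, rng):
        items = [(np.full((2, 2), v), lb) for v, lb in
                 [(0.0, "airflow"), (1.0, "touch")] for _ in range(40)]
        ds = build_dataset(items, rng)
        _, acc, auroc = train_svm(ds)
        assert acc == 1.0 and auroc == 1.0

    def test_single_class_training_rejected(self, rng):
        ds = build_dataset(toy_items(20, 20, rng), rng)
        ds.labels = np.zeros_like(ds.labels)
        with pytest.raises(DecodingError):
            train_svm(ds)


class TestRepetitions:
    def test_single_repetition_quantiles_degenerate(self, rng):
        items = toy_items(30, 30, rng, shift=1.0)
        res = evaluate_repetitions(lambda r: build_dataset(items, r),
                                   make_svm_factory(), n_rep=1, seed=0)
        q = res.quantiles
        assert q["q10"] == q["q50"] == q["q90"] == res.accuracies[0]

    def test_injected_accuracies_median(self):
        res = ClassifierResult(accuracies=np.array([0.5, 0.6, 0.7, 0.8, 0.9]),
                               aurocs=np.full(5, np.nan))
        assert res.quantiles["q50"] == pytest.approx(0.7)

    def test_fixed_master_seed_is_deterministic(self, rng):
        items = toy_items(40, 40, rng, shift=0.5)
        builder = lambda r: build_dataset(items, r)
        a = evaluate_repetitions(builder, make_svm_factory(), n_rep=4, seed=42)
        b = evaluate_repetitions(builder, make_svm_factory(), n_rep=4, seed=42)
        assert np.array_equal(a.accuracies, b.accuracies)
        assert np.array_equal(a.aurocs, b.aurocs)

    def test_class_balance_every_split_every_repetition(self, rng):
        items = toy_items(35, 23, rng)
        seen = []

        def factory(ds, r):
            for split in ("train", "val", "test"):
                y = ds.y(split)
                seen.append((y == 0).sum() == (y == 1).sum())
            return 0.5, 0.5

        evaluate_repetitions(lambda r: build_dataset(items, r), factory,
                             n_rep=5, seed=0)
        assert all(seen) and len(seen) == 15


def test_spectrograms_beat_raw_traces_for_band_effect(small_session):
    """Representation check: the same SVM decodes the band-power context
    better from spectrogram images than from raw time-series windows."""
    from spontlfp import select_windows

    wins, _ = select_windows(small_session)
    specs = session_spectrograms(small_session, wins, nucleus="basal",
                                 time_decim=25)
    raw_items = []
    for w in wins:
        if small_session.nucleus_of_channel[w.channel] != "basal":
            continue
        i0 = int(round(w.start * small_session.fs))
        n = int(round(w.length * small_session.fs))
        raw_items.append(
            (small_session.lfp[w.channel, i0:i0 + n].astype(float)[None, :],
             w.label))
    spec_accs, raw_accs = [], []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        _, a_spec, _ = train_svm(build_dataset(specs, rng))
        rng = np.random.default_rng(seed)
        _, a_raw, _ = train_svm(build_dataset(raw_items, rng))
        spec_accs.append(a_spec)
        raw_accs.append(a_raw)
    assert np.mean(spec_accs) > np.mean(raw_accs)
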