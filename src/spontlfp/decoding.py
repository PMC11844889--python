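"""Context decoding from spontaneous-window spectrograms.

Datasets group spectrograms by (session, nucleus); the minority class is
bootstrapped (resampled with replacement) to balance classes, an
80-10-10 train/validation/test split preserves equal class counts in
every split, and per-feature min–max scaling is fit on the training
split only.  Two classifiers are provided: a small CNN (two 3x3
convolution + ReLU stages with batch normalization, a 2x2 stride-1 max
pool, a 64-unit fully-connected layer with dropout, and a 2-unit
output), trained with Adam and cross-entropy for 40 epochs in batches
of 20 with lowest-validation-loss model selection; and an SVM on the
flattened images (RBF kernel, with a linear variant as negative
control).  The train/evaluate cycle is repeated (50 times by default)
with fresh splits and initializations, and accuracies are summarized by
their 10/50/90% quantiles plus per-repetition AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from . import nn
from .timefreq import CWTParams, Spectrogram, compute_spectrogram, restrict_band

LABEL_CODES = {"airflow": 0, "touch": 1}   # touch is the positive class


class DecodingError(ValueError):
    pass


class TrainingFailure(RuntimeError):
    def __init__(self, msg: str, history: Optional[dict] = None, repetition: Optional[int] = None):
        super().__init__(msg)
        self.history = history
        self.repetition = repetition


@dataclass
class CNNSpec:
    """Architecture of the spectrogram CNN (layer order is fixed)."""

    conv1_maps: int = 24
    conv2_maps: int = 48
    kernel_size: int = 3
    pool_size: int = 2
    pool_stride: int = 1     # stride-1 pooling as specified; 2 = conventional
    fc_units: int = 64
    dropout: float = 0.5
    n_classes: int = 2


@dataclass
class TrainConfig:
    batch_size: int = 20
    epochs: int = 40
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999


def decimate_time(values: np.ndarray, decim: int) -> np.ndarray:
    """Block-average spectrogram columns in groups of ``decim``."""
    if decim <= 1:
        return values
    f, t = values.shape
    t_out = t // decim
    return values[:, : t_out * decim].reshape(f, t_out, decim).mean(axis=2)


def session_spectrograms(
    session,
    windows: list,
    params: Optional[CWTParams] = None,
    nucleus: Optional[str] = None,
    time_decim: int = 25,
    band: Optional[tuple] = None,
) -> list:
    """Spectrogram images for every spontaneous window of a session.

    ``time_decim`` block-averages spectrogram columns (25 -> 40 Hz image
    time resolution at fs=1000), keeping classifier inputs CPU-sized.
    ``band=(lo, hi)`` optionally restricts the frequency rows.
    """
    params = params or CWTParams()
    keep = None if nucleus is None else set(session.channels_in(nucleus))
    specs = []
    for w in windows:
        if keep is not None and w.channel not in keep:
            continue
        i0 = int(round(w.start * session.fs))
        n = int(round(w.length * session.fs))
        sig = session.lfp[w.channel, i0:i0 + n].astype(float)
        spec = compute_spectrogram(sig, session.fs, params,
                                   trial_index=w.trial_index)
        spec.label = w.label
        spec.channel = w.channel
        spec.nucleus = session.nucleus_of_channel[w.channel]
        if band is not None:
            spec = restrict_band(spec, *band)
        spec.values = decimate_time(spec.values, time_decim)
        spec.times = spec.times[: spec.values.shape[1] * time_decim : time_decim]
        specs.append(spec)
    return specs


@dataclass
class SpectrogramDataset:
    """Balanced, split, train-scaled image dataset."""

    images: np.ndarray          # n x F x T (unscaled)
    labels: np.ndarray          # n, int codes
    idx_train: np.ndarray
    idx_val: np.ndarray
    idx_test: np.ndarray
    feat_min: np.ndarray        # per-feature, fit on train
    feat_max: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def image_shape(self) -> tuple:
        return self.images.shape[1:]

    def _scaled(self, idx: np.ndarray) -> np.ndarray:
        x = self.images[idx].reshape(idx.size, -1)
        rng_ = self.feat_max - self.feat_min
        rng_[rng_ == 0] = 1.0
        return (x - self.feat_min) / rng_

    def X_images(self, split: str) -> np.ndarray:
        idx = getattr(self, f"idx_{split}")
        return self._scaled(idx).reshape(idx.size, 1, *self.image_shape).astype(np.float32)

    def X_flat(self, split: str) -> np.ndarray:
        return self._scaled(getattr(self, f"idx_{split}"))

    def y(self, split: str) -> np.ndarray:
        return self.labels[getattr(self, f"idx_{split}")]

    def shuffled_labels(self, rng: np.random.Generator) -> "SpectrogramDataset":
        """Copy with training and validation labels randomly permuted
        (class counts preserved); test labels stay truthful."""
        labels = self.labels.copy()
        for idx in (self.idx_train, self.idx_val):
            labels[idx] = rng.permutation(labels[idx])
        return SpectrogramDataset(
            images=self.images, labels=labels,
            idx_train=self.idx_train, idx_val=self.idx_val, idx_test=self.idx_test,
            feat_min=self.feat_min, feat_max=self.feat_max,
            metadata={**self.metadata, "labels_shuffled": True})


def build_dataset(
    spectrograms: list,
    seed: int | np.random.Generator = 0,
    split: tuple = (0.8, 0.1, 0.1),
) -> SpectrogramDataset:
    """Balance, split and scale a set of labelled images.

    Accepts ``Spectrogram`` objects or ``(image_array, label)`` pairs.
    The minority class is resampled with replacement up to the majority
    count; the split keeps equal class counts in each subset; min–max
    scaling parameters come from the training split alone.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    images_by_label: dict = {}
    for item in spectrograms:
        if isinstance(item, Spectrogram):
            img, label = item.values, item.label
        else:
            img, label = item
        if label not in LABEL_CODES:
            raise DecodingError(f"unknown label {label!r}")
        images_by_label.setdefault(label, []).append(np.asarray(img, dtype=np.float64))
    missing = [lb for lb in LABEL_CODES if lb not in images_by_label]
    if missing:
        raise DecodingError(f"label(s) absent from dataset: {missing}")

    n_major = max(len(v) for v in images_by_label.values())
    per_class_idx = {}
    stacks = []
    labels = []
    offset = 0
    for label in LABEL_CODES:
        imgs = images_by_label[label]
        if len(imgs) < n_major:   # bootstrap the minority class
            extra = rng.integers(0, len(imgs), size=n_major - len(imgs))
            imgs = imgs + [imgs[i] for i in extra]
        stacks.extend(imgs)
        labels.extend([LABEL_CODES[label]] * n_major)
        per_class_idx[label] = np.arange(offset, offset + n_major)
        offset += n_major

    images = np.asarray(stacks)
    labels = np.asarray(labels, dtype=np.int64)

    n = n_major
    n_val = int(round(split[1] * n))
    n_test = int(round(split[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise DecodingError(f"too few items per class ({n}) for an {split} split")
    tr, va, te = [], [], []
    for label in LABEL_CODES:
        perm = rng.permutation(per_class_idx[label])
        tr.append(perm[:n_train])
        va.append(perm[n_train:n_train + n_val])
        te.append(perm[n_train + n_val:])
    idx_train = np.concatenate(tr)
    idx_val = np.concatenate(va)
    idx_test = np.concatenate(te)

    flat_train = images[idx_train].reshape(idx_train.size, -1)
    ds = SpectrogramDataset(
        images=images, labels=labels,
        idx_train=idx_train, idx_val=idx_val, idx_test=idx_test,
        feat_min=flat_train.min(axis=0), feat_max=flat_train.max(axis=0),
        metadata={"n_per_class": n, "split": split})
    return ds


def build_cnn(input_shape: tuple, spec: Optional[CNNSpec] = None,
              rng: int | np.random.Generator = 0) -> nn.Sequential:
    """Instantiate the spectrogram CNN for single-channel images.

    Layer order: Conv(3x3, 24) + ReLU, BatchNorm, Conv(3x3, 48) + ReLU,
    MaxPool(2x2, stride 1), BatchNorm, Flatten, FC(64), Dropout, FC(2).
    Convolutions are valid (unpadded), stride 1.
    """
    spec = spec or CNNSpec()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    h, w = input_shape
    k, p, ps = spec.kernel_size, spec.pool_size, spec.pool_stride
    h1, w1 = h - k + 1, w - k + 1
    h2, w2 = h1 - k + 1, w1 - k + 1
    h3 = (h2 - p) // ps + 1
    w3 = (w2 - p) // ps + 1
    if min(h3, w3) < 1:
        raise DecodingError(
            f"input {h}x{w} too small for two {k}x{k} valid convolutions "
            f"plus a {p}x{p} pool")
    model = nn.Sequential([
        nn.Conv2d(1, spec.conv1_maps, k, rng),
        nn.ReLU(),
        nn.BatchNorm2d(spec.conv1_maps),
        nn.Conv2d(spec.conv1_maps, spec.conv2_maps, k, rng),
        nn.ReLU(),
        nn.MaxPool2d(p, ps),
        nn.BatchNorm2d(spec.conv2_maps),
        nn.Flatten(),
        nn.Linear(spec.conv2_maps * h3 * w3, spec.fc_units, rng),
        nn.ReLU(),
        nn.Dropout(spec.dropout, rng),
        nn.Linear(spec.fc_units, spec.n_classes, rng),
    ])
    model.layer_shapes = {
        "conv1": (h1, w1, spec.conv1_maps),
        "conv2": (h2, w2, spec.conv2_maps),
        "pool": (h3, w3, spec.conv2_maps),
    }
    return model


def _epoch_loss(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
                batch: int = 256) -> float:
    total, n = 0.0, 0
    for i in range(0, X.shape[0], batch):
        logits = model.forward(X[i:i + batch], train=False)
        loss, _ = nn.cross_entropy(logits, y[i:i + batch])
        total += loss * (logits.shape[0])
        n += logits.shape[0]
    return total / n


def train_classifier(
    model: nn.Sequential,
    dataset: SpectrogramDataset,
    cfg: Optional[TrainConfig] = None,
    rng: int | np.random.Generator = 0,
) -> tuple:
    """Train the CNN; return ``(model, history)``.

    The returned model carries the parameter snapshot with the lowest
    validation loss across epochs.  History records per-epoch mean
    training loss and validation loss.  Non-finite losses abort with a
    :class:`TrainingFailure` carrying the partial history.
    """
    cfg = cfg or TrainConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    Xtr, ytr = dataset.X_images("train"), dataset.y("train")
    Xva, yva = dataset.X_images("val"), dataset.y("val")
    if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
        raise DecodingError("dataset splits are not populated")
    opt = nn.Adam(model.parameters(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    history = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_state = model.state()
    for epoch in range(cfg.epochs):
        order = rng.permutation(Xtr.shape[0])
        losses = []
        for i in range(0, order.size, cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            logits = model.forward(Xtr[sel], train=True)
            loss, dlogits = nn.cross_entropy(logits, ytr[sel])
            if not np.isfinite(loss):
                history["train_loss"].append(loss)
                raise TrainingFailure(f"non-finite training loss at epoch {epoch}",
                                      history=history)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_loss = _epoch_loss(model, Xva, yva)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        if not np.isfinite(val_loss):
            raise TrainingFailure(f"non-finite validation loss at epoch {epoch}",
                                  history=history)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state()
    model.load_state(best_state)
    return model, history


def evaluate_model(model: nn.Sequential, dataset: SpectrogramDataset) -> tuple:
    """Test-set accuracy and AUROC (touch-probability score)."""
    Xte, yte = dataset.X_images("test"), dataset.y("test")
    logits = model.forward(Xte, train=False)
    proba = nn.softmax(logits)[:, LABEL_CODES["touch"]]
    acc = float((logits.argmax(axis=1) == yte).mean())
    auroc = float(roc_auc_score(yte, proba)) if np.unique(yte).size > 1 else np.nan
    return acc, auroc


def train_svm(dataset: SpectrogramDataset, kernel: str = "rbf", C: float = 1.0):
    """SVM on flattened scaled images (dual formulation via libsvm).

    Kernel width uses the variance-scale rule (``gamma="scale"``).
    Returns ``(classifier, test_accuracy, auroc)``.
    """
    if kernel not in ("rbf", "linear"):
        raise DecodingError("kernel must be 'rbf' or 'linear'")
    ytr = dataset.y("train")
    if np.unique(ytr).size < 2:
        raise DecodingError("training data contains a single class")
    clf = SVC(kernel=kernel, C=C, gamma="scale")
    clf.fit(dataset.X_flat("train"), ytr)
    Xte, yte = dataset.X_flat("test"), dataset.y("test")
    acc = float(clf.score(Xte, yte))
    score = clf.decision_function(Xte)
    auroc = float(roc_auc_score(yte, score)) if np.unique(yte).size > 1 else np.nan
    return clf, acc, auroc


@dataclass
class ClassifierResult:
    accuracies: np.ndarray
    aurocs: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def quantiles(self) -> dict:
        q10, q50, q90 = np.quantile(self.accuracies, [0.1, 0.5, 0.9])
        return {"q10": float(q10), "q50": float(q50), "q90": float(q90)}

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "accuracies": np.asarray(self.accuracies).tolist(),
            "aurocs": np.asarray(self.aurocs).tolist(),
            "quantiles": self.quantiles,
            "metadata": self.metadata,
        }


def evaluate_repetitions(
    dataset_builder: Callable,
    classifier_factory: Callable,
    n_rep: int = 50,
    seed: int = 0,
    metadata: Optional[dict] = None,
) -> ClassifierResult:
    """Repeat split → init → train → test ``n_rep`` times.

    ``dataset_builder(rng)`` must return a fresh :class:`SpectrogramDataset`
    (new random split) and ``classifier_factory(dataset, rng)`` must return
    ``(accuracy, auroc)``.  Each repetition draws an independent child
    stream of ``seed``; a fixed seed gives identical results.
    """
    if n_rep < 1:
        raise DecodingError("n_rep must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_rep)
    accs, aurocs = [], []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            ds = dataset_builder(rng)
            acc, auroc = classifier_factory(ds, rng)
        except TrainingFailure as err:
            raise TrainingFailure(str(err), history=err.history, repetition=r) from err
        accs.append(acc)
        aurocs.append(auroc)
    return ClassifierResult(accuracies=np.asarray(accs), aurocs=np.asarray(aurocs),
                            metadata={"n_rep": n_rep, "seed": seed, **(metadata or {})})


def make_cnn_factory(spec: Optional[CNNSpec] = None,
                     cfg: Optional[TrainConfig] = None) -> Callable:
    def factory(dataset: SpectrogramDataset, rng: np.random.Generator) -> tuple:
        model = build_cnn(dataset.image_shape, spec, rng)
        model, _ = train_classifier(model, dataset, cfg, rng)
        return evaluate_model(model, dataset)

    return factory


def make_svm_factory(kernel: str = "rbf", C: float = 1.0) -> Callable:
    def factory(dataset: SpectrogramDataset, rng: np.random.Generator) -> tuple:
        _, acc, auroc = train_svm(dataset, kernel=kernel, C=C)
        return acc, auroc

    return factory
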