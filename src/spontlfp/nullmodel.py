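"""Shuffled-label null distributions and cross-nucleus statistics.

The significance reference for a decoder is a bootstrap null: training
(and validation) labels are randomly reassigned equally between the two
classes, the model is trained per protocol, and accuracy is measured on
the *true-labelled* test set.  This estimates the chance of spuriously
high accuracy from correlated noise rather than from context.

Across nuclei, per-repetition accuracy samples are compared with the
Kruskal–Wallis H-test (one-way ANOVA on ranks, tie-corrected), and the
dependence of accuracy on electrode yield is summarized by a Spearman
rank correlation between median accuracy and contact count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .decoding import ClassifierResult, SpectrogramDataset


class NullModelError(ValueError):
    pass


@dataclass
class NullDistribution:
    accuracies: np.ndarray
    n_shuffles: int
    metadata: dict = field(default_factory=dict)

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def max(self) -> float:
        return float(np.max(self.accuracies))

    @property
    def min(self) -> float:
        return float(np.min(self.accuracies))

    def to_dict(self) -> dict:
        return {"accuracies": np.asarray(self.accuracies).tolist(),
                "n_shuffles": self.n_shuffles, "metadata": self.metadata}


def bootstrap_null(
    dataset_builder: Callable,
    classifier_factory: Callable,
    n_shuffles: int = 20,
    seed: int = 0,
    metadata: Optional[dict] = None,
) -> NullDistribution:
    """Accuracy distribution under shuffled training labels.

    Per shuffle: a fresh dataset split is drawn, training and validation
    labels are permuted (equal class assignment preserved — the splits
    are class-balanced), the classifier is trained per protocol, and
    accuracy is evaluated on the untouched test labels.
    """
    if n_shuffles < 1:
        raise NullModelError("n_shuffles must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_shuffles)
    accs = []
    for child in children:
        rng = np.random.default_rng(child)
        ds: SpectrogramDataset = dataset_builder(rng)
        shuffled = ds.shuffled_labels(rng)
        acc, _ = classifier_factory(shuffled, rng)
        accs.append(acc)
    return NullDistribution(accuracies=np.asarray(accs), n_shuffles=n_shuffles,
                            metadata={"seed": seed, "shuffle_validation": True,
                                      **(metadata or {})})


def compare_nuclei(results: dict) -> tuple:
    """Kruskal–Wallis H-test on accuracy samples grouped by nucleus.

    ``results`` maps nucleus → :class:`ClassifierResult` or accuracy
    array.  Returns ``(H, p)``.  When every observation across all
    groups is identical the tie correction degenerates; by convention
    that case returns ``H = 0, p = 1`` (no rank separation).
    """
    groups = []
    for nucleus, res in results.items():
        vals = np.asarray(res.accuracies if isinstance(res, ClassifierResult) else res,
                          dtype=float)
        if vals.size < 2:
            raise NullModelError(f"nucleus {nucleus!r} has fewer than 2 accuracy values")
        groups.append(vals)
    if len(groups) < 2:
        raise NullModelError("need at least 2 nuclei to compare")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def accuracy_channel_correlation(results: list) -> tuple:
    """Spearman correlation of median accuracy vs. contact count.

    ``results`` is a sequence of ``(median_accuracy, n_channels)`` pairs
    or of :class:`ClassifierResult` with ``n_channels`` metadata.
    """
    pairs = []
    for item in results:
        if isinstance(item, ClassifierResult):
            pairs.append((item.median_accuracy, item.metadata["n_channels"]))
        else:
            pairs.append((float(item[0]), float(item[1])))
    if len(pairs) < 3:
        raise NullModelError("need at least 3 (accuracy, n_channels) pairs")
    acc, nch = map(np.asarray, zip(*pairs))
    if np.ptp(nch) == 0:
        raise NullModelError("channel counts are constant; correlation undefined")
    rho, p = stats.spearmanr(nch, acc)
    return float(rho), float(p)


def summary_table(results: dict, nulls: Optional[dict] = None):
    """Per-(session, nucleus) quantile summary with null extremes (CSV-ready)."""
    import pandas as pd

    rows = []
    for key, res in results.items():
        session, nucleus = key if isinstance(key, tuple) else (res.metadata.get("session"), key)
        q = res.quantiles
        null = (nulls or {}).get(key)
        rows.append({
            "session": session, "nucleus": nucleus,
            "q10": q["q10"], "q50": q["q50"], "q90": q["q90"],
            "null_min": null.min if null is not None else np.nan,
            "null_max": null.max if null is not None else np.nan,
        })
    return pd.DataFrame(rows)
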