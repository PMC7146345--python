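"""Evaluation protocol: proportion criterion, cross-validation, sweeps.

The recordings carry no per-point ground-truth labels, only the known
number and duration of repetitions per movement set; the proportion
criterion therefore compares the fraction of points the model assigns to
a set's movement against the expected fraction derived from the
repetition annotations.  Instance-level accuracy, macro F1 and a
row-normalized confusion matrix come from stratified fivefold
cross-validation over the 900 single-repetition instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .config import RunConfig, default_config
from .model import UNKNOWN, HybridClusteringModel
from .synth import Dataset


@dataclass
class ProportionReport:
    """Per-set expected vs predicted movement-point proportions."""

    table: pd.DataFrame  # columns: set_id, movement, expected, predicted, abs_diff
    score: float  # 1 - mean absolute difference


@dataclass
class EvalReport:
    """Cross-validation outcome."""

    confusion: np.ndarray  # row-normalized, class x class
    accuracy: float  # instance-level
    point_accuracy: float
    f1_macro: float
    precision: np.ndarray
    recall: np.ndarray
    classes: list[int]
    fold_results: list[dict] = field(default_factory=list)

    def plot_confusion(self, ax=None):
        """Heatmap of the normalized confusion matrix (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.confusion, cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.classes)), self.classes)
        ax.set_yticks(range(len(self.classes)), self.classes)
        ax.set_xlabel("predicted movement")
        ax.set_ylabel("true movement")
        ax.figure.colorbar(im, ax=ax)
        return ax


def proportion_difference(expected: float, predicted: float) -> float:
    """Absolute difference of two movement-point proportions."""
    for p in (expected, predicted):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportions must lie in [0, 1], got {p}")
    return abs(expected - predicted)


def proportion_criterion(predicted_by_set: dict, truth_by_set: dict) -> ProportionReport:
    """Proportion-accuracy criterion over movement sets.

    ``predicted_by_set`` maps set id -> per-point predicted labels;
    ``truth_by_set`` maps set id -> (movement_id, per-point true mask or
    labels).  For each set the expected proportion is the fraction of
    points truly inside a repetition of the set's movement and the
    predicted proportion is the fraction of points labelled as it.
    """
    rows = []
    for set_id in sorted(predicted_by_set):
        pred = np.asarray(predicted_by_set[set_id])
        mov, truth = truth_by_set[set_id]
        truth = np.asarray(truth)
        if len(pred) != len(truth):
            raise ValueError(f"set {set_id}: predicted length {len(pred)} != truth length {len(truth)}")
        expected = float(np.mean(truth == mov)) if truth.dtype.kind in "iu" else float(np.mean(truth))
        predicted = float(np.mean(pred == mov))
        rows.append({"set_id": set_id, "movement": mov, "expected": expected,
                     "predicted": predicted, "abs_diff": abs(expected - predicted)})
    table = pd.DataFrame(rows)
    return ProportionReport(table=table, score=1.0 - float(table["abs_diff"].mean()))


def confusion_and_f1(predicted, true, classes=None) -> EvalReport:
    """Row-normalized confusion matrix and macro precision/recall/F1."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if len(predicted) != len(true):
        raise ValueError(f"length mismatch: {len(predicted)} vs {len(true)}")
    if classes is None:
        classes = sorted(set(np.unique(true).tolist()))
    unseen = set(np.unique(predicted).tolist()) - set(classes) - {UNKNOWN}
    if unseen:
        raise ValueError(f"predicted labels {sorted(unseen)} outside the class set {classes}")
    cm = confusion_matrix(true, predicted, labels=list(classes) + [UNKNOWN])[: len(classes)]
    row = cm.sum(axis=1, keepdims=True).astype(float)
    row[row == 0] = 1.0
    norm = cm / row
    prec, rec, f1, _ = precision_recall_fscore_support(
        true, predicted, labels=list(classes), average=None, zero_division=0.0
    )
    acc = float(np.mean(predicted == true))
    return EvalReport(
        confusion=norm[:, : len(classes)],
        accuracy=acc,
        point_accuracy=acc,
        f1_macro=float(np.mean(f1)),
        precision=prec,
        recall=rec,
        classes=list(classes),
    )


def stratified_folds(dataset: Dataset, folds: int, seed: int) -> list[np.ndarray]:
    """Partition instance indices into folds, stratified by (class, subject).

    Every instance appears in exactly one fold.
    """
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(dataset.instances):
        groups.setdefault((rec.class_id, rec.subject), []).append(i)
    if any(len(g) < folds for g in groups.values()):
        raise ValueError(f"every (class, subject) group needs >= {folds} instances")
    rng = np.random.default_rng(seed)
    fold_idx: list[list[int]] = [[] for _ in range(folds)]
    for key in sorted(groups):
        idx = np.array(groups[key])
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, folds)):
            fold_idx[f].extend(chunk.tolist())
    return [np.array(sorted(f)) for f in fold_idx]


def _default_model_factory(train, config, seed):
    return HybridClusteringModel(train, config=config).fit(seed=seed)


def crossval(dataset: Dataset, config: RunConfig | None = None, folds: int = 5,
             seed: int = 0, model_factory=None) -> EvalReport:
    """Stratified k-fold cross-validation at instance level.

    Each fold fits the model on the training instances and labels every
    held-out instance (majority vote over its segments); the reported
    accuracy is the mean over folds of the instance-level accuracy, with
    UNKNOWN predictions counted as errors.  Per-point accuracy is
    reported alongside.  Identical seeds give identical partitions and
    identical per-layer seeds, so a rerun is bit-reproducible.
    """
    config = config or default_config(seed=seed)
    model_factory = model_factory or _default_model_factory
    fold_idx = stratified_folds(dataset, folds, seed)
    classes = dataset.class_ids()

    all_true, all_pred = [], []
    fold_results = []
    point_hits = point_total = 0
    for f, test_idx in enumerate(fold_idx):
        test_set = set(test_idx.tolist())
        train = [(r.class_id, r.series) for i, r in enumerate(dataset.instances) if i not in test_set]
        res = model_factory(train, config, seed + 1000 * (f + 1))
        t, p = [], []
        for i in test_idx:
            rec = dataset.instances[i]
            lab = res.predict_instance(rec.series)
            t.append(rec.class_id)
            p.append(lab)
            n = len(rec.series)
            point_total += n
            if lab == rec.class_id:
                point_hits += n
        t, p = np.array(t), np.array(p)
        fold_results.append({"fold": f, "n_test": len(t), "accuracy": float(np.mean(t == p))})
        all_true.append(t)
        all_pred.append(p)

    true = np.concatenate(all_true)
    pred = np.concatenate(all_pred)
    rep = confusion_and_f1(pred, true, classes=classes)
    rep.accuracy = float(np.mean([fr["accuracy"] for fr in fold_results]))
    rep.point_accuracy = point_hits / point_total if point_total else 0.0
    rep.fold_results = fold_results
    return rep


def sweep_k1(dataset: Dataset, k_values, config: RunConfig | None = None,
             seed: int = 0) -> pd.DataFrame:
    """Fit the model on the full dataset for each first-layer cluster count.

    Scores each k by the training proportion criterion (the quantity the
    protocol uses for parameter search).  Returns a (k, score) table with
    the argmax flagged.
    """
    from dataclasses import replace

    config = config or default_config(seed=seed)
    if not len(list(k_values)):
        raise ValueError("k_values must be non-empty")
    rows = []
    for k in k_values:
        # the sub-feature layer can never be finer than the encode layer
        cfg = replace(config, model=replace(config.model, k1=int(k),
                                            k2=min(config.model.k2, int(k))))
        res = HybridClusteringModel(dataset, config=cfg).fit(seed=seed)
        rows.append({"k": int(k), "score": res.training_score})
    table = pd.DataFrame(rows)
    table["best"] = table["score"] == table["score"].max()
    return table
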