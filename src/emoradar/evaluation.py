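"""Classification metrics, cross-validation, ROC/AUC and split protocols.

Metric conventions: multi-class confusion matrices are reduced one-vs-rest
per class; precision = TP/(TP+FP), recall = TP/(TP+FN), F-score is the
harmonic mean of the two, and accuracy is the diagonal mass of the matrix.
A class whose denominator is empty gets NaN for that metric, is excluded
from the macro average, and triggers an ``UndefinedMetricWarning``.

Leave-one-out cross-validation reports each fold both as squared error on
the one-hot probability target (MSE) and as 0/1 correctness; the aggregate
is the plain mean over folds.

Split protocols: ``person_dependent`` stratifies within each
(label, subject) group so every subject appears in train, validation and
test; ``person_independent`` holds out whole subjects so no test subject is
ever seen in training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .synthgen import EMOTIONS

__all__ = [
    "ConfusionMatrix", "MetricReport", "CVResult", "UndefinedMetricWarning",
    "confusion", "metrics", "loocv", "roc_auc", "split_protocols",
]


class UndefinedMetricWarning(UserWarning):
    """A per-class metric had an empty denominator and was skipped."""


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Integer counts; rows = true label, columns = predicted label."""

    counts: np.ndarray
    labels: tuple = EMOTIONS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.shape[0] != len(self.labels):
            raise ValueError("matrix size must match the label list")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against the rest."""
        c = self.counts
        tp = int(c[class_index, class_index])
        fp = int(c[:, class_index].sum() - tp)
        fn = int(c[class_index, :].sum() - tp)
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, fn, tn

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(counts=df.to_numpy(dtype=int), labels=tuple(df.columns))


def _to_indices(labels: Sequence, label_names: tuple) -> np.ndarray:
    to_idx = {lab: i for i, lab in enumerate(label_names)}
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in to_idx:
                raise ValueError(f"unknown label {lab!r}")
            out.append(to_idx[lab])
        else:
            i = int(lab)
            if not (0 <= i < len(label_names)):
                raise ValueError(f"label index {i} out of range")
            out.append(i)
    return np.asarray(out, dtype=int)


def confusion(y_true: Sequence, y_pred: Sequence,
              labels: tuple = EMOTIONS) -> ConfusionMatrix:
    """Count (true, predicted) pairs; accepts label names or indices."""
    ti = _to_indices(y_true, labels)
    pi = _to_indices(y_pred, labels)
    if len(ti) != len(pi):
        raise ValueError("true and predicted label lists differ in length")
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts=counts, labels=labels)


# ---------------------------------------------------------------------------
# metrics (accuracy, precision, recall, F-score)
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    accuracy: float
    precision: dict          # class name -> value (NaN when undefined)
    recall: dict
    f_score: dict
    macro_precision: float
    macro_recall: float
    macro_f_score: float
    labels: tuple = EMOTIONS

    def to_json(self, path=None) -> str:
        payload = {k: getattr(self, k) for k in
                   ("accuracy", "precision", "recall", "f_score",
                    "macro_precision", "macro_recall", "macro_f_score")}
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> None:
        rows = [dict(label=lab, precision=self.precision[lab],
                     recall=self.recall[lab], f_score=self.f_score[lab])
                for lab in self.labels]
        rows.append(dict(label="macro", precision=self.macro_precision,
                         recall=self.macro_recall, f_score=self.macro_f_score))
        pd.DataFrame(rows).to_csv(path, index=False)


def _safe_ratio(num: int, den: int, what: str, label) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {label!r} "
                      "(empty denominator); excluded from macro average",
                      UndefinedMetricWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """One-vs-rest precision/recall/F per class plus accuracy and macros.

    Convention: F-score is 0 (not NaN) when precision and recall are both
    defined and both zero; NaN propagates only from undefined components.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision, recall, f_score = {}, {}, {}
    for i, lab in enumerate(cm.labels):
        tp, fp, fn, _ = cm.one_vs_rest(i)
        p = _safe_ratio(tp, tp + fp, "precision", lab)
        r = _safe_ratio(tp, tp + fn, "recall", lab)
        precision[lab], recall[lab] = p, r
        if np.isnan(p) or np.isnan(r):
            f_score[lab] = float("nan")
        elif p + r == 0:
            f_score[lab] = 0.0
        else:
            f_score[lab] = 2 * p * r / (p + r)

    def macro(d: dict) -> float:
        vals = [v for v in d.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return MetricReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        precision=precision, recall=recall, f_score=f_score,
        macro_precision=macro(precision), macro_recall=macro(recall),
        macro_f_score=macro(f_score), labels=cm.labels)


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Accuracy/precision/recall/F from raw binary counts (convenience)."""
    cm = ConfusionMatrix(counts=np.array([[tn, fp], [fn, tp]]),
                         labels=("negative", "positive"))
    rep = metrics(cm)
    return dict(accuracy=rep.accuracy,
                precision=rep.precision["positive"],
                recall=rep.recall["positive"],
                f_score=rep.f_score["positive"])


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_mse: list = field(default_factory=list)
    fold_correct: list = field(default_factory=list)   # 0/1 per fold
    labels: tuple = EMOTIONS

    @property
    def n_folds(self) -> int:
        return len(self.fold_mse)

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.fold_mse))

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_correct))

    def to_csv(self, path) -> None:
        pd.DataFrame(dict(fold=np.arange(self.n_folds),
                          mse=self.fold_mse,
                          correct=self.fold_correct)).to_csv(path, index=False)


def loocv(samples: Sequence, build_and_fit: Callable,
          labels: tuple = EMOTIONS) -> CVResult:
    """Leave-one-out CV: n folds, each holding out exactly one sample.

    ``build_and_fit(train_samples)`` must return a callable
    ``predict(sample) -> probability vector`` over ``labels``. Each fold
    contributes the mean squared error of that vector against the held-out
    one-hot target and a 0/1 correctness flag.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("LOOCV needs at least two samples")
    to_idx = {lab: i for i, lab in enumerate(labels)}
    result = CVResult(labels=labels)
    for i in range(n):
        train = [s for j, s in enumerate(samples) if j != i]
        predict = build_and_fit(train)
        probs = np.asarray(predict(samples[i]), dtype=float)
        if probs.shape != (len(labels),):
            raise ValueError("predictor must return one probability per class")
        onehot = np.zeros(len(labels))
        onehot[to_idx[samples[i].label]] = 1.0
        result.fold_mse.append(float(np.mean((probs - onehot) ** 2)))
        result.fold_correct.append(
            int(int(np.argmax(probs)) == to_idx[samples[i].label]))
    return result


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, y_true: Sequence,
            labels: tuple = EMOTIONS) -> dict:
    """One-vs-rest ROC per class.

    ``scores`` is (n, n_classes). Returns ``{"auc": {class: value},
    "macro_auc": value, "curves": {class: DataFrame(fpr, tpr, threshold)}}``.
    Classes absent from ``y_true`` (or covering all of it) get NaN AUC and
    are excluded from the macro average.
    """
    s = np.asarray(scores, dtype=float)
    ti = _to_indices(y_true, labels)
    if s.ndim != 2 or s.shape != (len(ti), len(labels)):
        raise ValueError("scores must be (n_samples, n_classes)")
    aucs, curves = {}, {}
    for i, lab in enumerate(labels):
        binary = (ti == i).astype(int)
        if binary.min() == binary.max():
            warnings.warn(f"AUC undefined for class {lab!r}: only one "
                          "true class present", UndefinedMetricWarning,
                          stacklevel=2)
            aucs[lab] = float("nan")
            continue
        aucs[lab] = float(roc_auc_score(binary, s[:, i]))
        fpr, tpr, thr = roc_curve(binary, s[:, i])
        curves[lab] = pd.DataFrame(dict(fpr=fpr, tpr=tpr, threshold=thr))
    defined = [v for v in aucs.values() if not np.isnan(v)]
    return dict(auc=aucs,
                macro_auc=float(np.mean(defined)) if defined else float("nan"),
                curves=curves)


def save_roc_curves(result: dict, path) -> None:
    """Flatten the per-class ROC points into one CSV (fpr, tpr, threshold, class)."""
    frames = []
    for lab, df in result["curves"].items():
        d = df.copy()
        d["class"] = lab
        frames.append(d)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:  # every class was degenerate (e.g. a tiny test split)
        out = pd.DataFrame(columns=["fpr", "tpr", "threshold", "class"])
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# split protocols
# ---------------------------------------------------------------------------

def _quota_allocation(group_sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across groups."""
    if total == 0:
        return np.zeros(len(group_sizes), dtype=int)
    share = group_sizes * total / group_sizes.sum()
    base = np.floor(share).astype(int)
    base = np.minimum(base, group_sizes)
    short = total - base.sum()
    order = np.argsort(-(share - base), kind="stable")
    for g in order:
        if short == 0:
            break
        if base[g] < group_sizes[g]:
            base[g] += 1
            short -= 1
    return base


def split_protocols(labels: Sequence, subject_ids: Sequence, mode: str,
                    fractions: tuple = (0.8, 0.1, 0.1),
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train/validation/test index sets for the two evaluation protocols.

    ``person_dependent``: within every (label, subject) group, samples are
    split across the three sets, so each subject is seen during training.
    ``person_independent``: whole subjects are assigned to exactly one set,
    so test subjects are never seen in training. Validation and test sizes
    are round(fraction * n); train takes the remainder (864 samples at
    (0.8, 0.1, 0.1) -> 692/86/86).
    """
    if mode not in ("person_dependent", "person_independent"):
        raise ValueError("mode must be person_dependent or person_independent")
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    labs = np.asarray(list(labels))
    subs = np.asarray(list(subject_ids))
    if labs.shape != subs.shape:
        raise ValueError("labels and subject_ids differ in length")
    n = len(labs)
    rng = np.random.default_rng(seed)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    if n_val + n_test >= n:
        raise ValueError("validation + test would consume the whole dataset")

    if mode == "person_dependent":
        groups: dict[tuple, list[int]] = {}
        for i in range(n):
            groups.setdefault((labs[i], subs[i]), []).append(i)
        keys = sorted(groups, key=str)
        sizes = np.asarray([len(groups[k]) for k in keys])
        q_test = _quota_allocation(sizes, n_test)
        q_val = _quota_allocation(sizes - q_test, n_val)
        test_idx, val_idx, train_idx = [], [], []
        for g, k in enumerate(keys):
            idx = np.asarray(groups[k])
            rng.shuffle(idx)
            test_idx.extend(idx[:q_test[g]])
            val_idx.extend(idx[q_test[g]:q_test[g] + q_val[g]])
            train_idx.extend(idx[q_test[g] + q_val[g]:])
    else:
        subjects = sorted(set(subs.tolist()), key=str)
        rng.shuffle(subjects)
        counts = {s: int((subs == s).sum()) for s in subjects}
        test_subj, val_subj = [], []
        acc = 0
        it = iter(subjects)
        for s in it:
            if acc >= n_test:
                val_acc = 0
                for s2 in [s] + list(it):
                    if val_acc >= n_val:
                        break
                    val_subj.append(s2)
                    val_acc += counts[s2]
                break
            test_subj.append(s)
            acc += counts[s]
        if not val_subj or len(test_subj) + len(val_subj) >= len(subjects):
            raise ValueError("too few subjects for a person-independent split")
        test_idx = [i for i in range(n) if subs[i] in test_subj]
        val_idx = [i for i in range(n) if subs[i] in val_subj]
        train_idx = [i for i in range(n)
                     if subs[i] not in test_subj and subs[i] not in val_subj]

    return (np.sort(np.asarray(train_idx, dtype=int)),
            np.sort(np.asarray(val_idx, dtype=int)),
            np.sort(np.asarray(test_idx, dtype=int)))
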