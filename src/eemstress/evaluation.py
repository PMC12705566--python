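"""Splits, confusion matrices, one-vs-rest metrics, and the excitation sweep.

Metrics follow the multiclass one-vs-rest convention: for class c,
sensitivity = TP_c / (true count of c) and specificity = TN_c / (TN_c + FP_c)
with false positives counted column-wise (predictions into c from other rows).
Overall accuracy is trace/total. These definitions reproduce the published
per-class worked examples exactly, which is asserted in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split

from .attention import AttentionConfig
from .core import EEMDataset
from .models import train_attention_classifier

__all__ = [
    "DatasetSplit",
    "ConfusionMatrix",
    "ClassMetrics",
    "split_dataset",
    "confusion",
    "class_metrics",
    "excitation_sweep",
]

CLASS_ORDER = (0, 10, 100)


@dataclass
class DatasetSplit:
    """Stratified calibration/validation indices plus CV folds on calibration."""

    calibration: np.ndarray
    validation: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def split_dataset(labels, ratios=(2 / 3, 1 / 3), k_folds: int = 5, seed: int = 0) -> DatasetSplit:
    """Stratified calibration/validation split with k-fold CV on calibration.

    ``labels`` is a per-sample class sequence or an :class:`EEMDataset`
    (stratified by concentration). ``ratios`` = (calibration, validation)
    fractions summing to 1. Deterministic given ``seed``.
    """
    if isinstance(labels, EEMDataset):
        labels = labels.concentrations()
    y = np.asarray(labels)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(y)
    idx = np.arange(n)
    if ratios[1] <= 0:
        warnings.warn("validation fraction is 0: validation set is empty", RuntimeWarning)
        cal, val = idx, np.array([], dtype=int)
    else:
        cal, val = train_test_split(idx, test_size=ratios[1], stratify=y, random_state=seed)
        cal, val = np.sort(cal), np.sort(val)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if k_folds and k_folds > 1:
        counts = np.bincount(np.unique(y[cal], return_inverse=True)[1])
        if counts.min() < k_folds:
            raise ValueError(
                f"a class has only {counts.min()} calibration samples, fewer than k_folds={k_folds}"
            )
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        folds = [(cal[tr], cal[te]) for tr, te in skf.split(cal, y[cal])]
    return DatasetSplit(calibration=cal, validation=val, folds=folds)


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class and columns = predicted class."""

    counts: np.ndarray
    class_order: tuple = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for class order {self.class_order}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{c} mg/L" for c in self.class_order]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def confusion(true_labels, predicted_labels, class_order=CLASS_ORDER) -> ConfusionMatrix:
    """Count matrix[i][j] = #(true == class_i and predicted == class_j)."""
    y_t, y_p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y_t.shape != y_p.shape:
        raise ValueError("label sequences must have equal length")
    known = set(class_order)
    stray = sorted({*np.unique(y_t).tolist(), *np.unique(y_p).tolist()} - known)
    if stray:
        raise ValueError(f"labels {stray} not in class order {class_order}")
    if y_t.size == 0:
        return ConfusionMatrix(np.zeros((len(class_order),) * 2, dtype=int), tuple(class_order))
    counts = _sk_confusion(y_t, y_p, labels=list(class_order))
    return ConfusionMatrix(counts, tuple(class_order))


@dataclass
class ClassMetrics:
    """Per-class sensitivity/specificity and overall accuracy, in percent."""

    sensitivity: dict
    specificity: dict
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sensitivity_pct": self.sensitivity, "specificity_pct": self.specificity}
        )


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest metrics from a confusion matrix (NaN flags an empty class)."""
    M = cm.counts
    total = M.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    sens, spec = {}, {}
    for i, c in enumerate(cm.class_order):
        row = M[i].sum()
        tp = M[i, i]
        fp = M[:, i].sum() - tp
        tn = total - row - fp
        sens[c] = 100.0 * tp / row if row else float("nan")
        spec[c] = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    accuracy = 100.0 * np.trace(M) / total
    return ClassMetrics(sensitivity=sens, specificity=spec, accuracy=float(accuracy))


def excitation_sweep(
    dataset: EEMDataset,
    config: AttentionConfig | None = None,
    ex_list=None,
    split: DatasetSplit | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Validation accuracy of 1-D attention models per excitation wavelength.

    For each wavelength the emission slices form the inputs of a fresh
    sequence classifier; the returned frame has columns (ex_nm, accuracy_pct)
    in the order of ``ex_list``. Deterministic given ``seed``/config seed.
    """
    config = config or AttentionConfig()
    grid = dataset.grid
    if ex_list is None:
        ex_list = grid.ex_axis[::4]  # every 20 nm on the default grid
    y = dataset.concentrations()
    if split is None:
        split = split_dataset(y, k_folds=0, seed=seed)
    tensor = dataset.to_tensor()
    rows = []
    for ex in ex_list:
        r = grid.ex_index(float(ex))
        X = tensor[:, r, :]
        cfg = AttentionConfig(**{**config.__dict__, "seed": config.seed + r})
        clf = train_attention_classifier(X[split.calibration], y[split.calibration], cfg, view="sequence")
        pred = clf.predict(X[split.validation])
        acc = 100.0 * float(np.mean(pred == y[split.validation]))
        rows.append({"ex_nm": float(ex), "accuracy_pct": acc})
    return pd.DataFrame(rows)
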