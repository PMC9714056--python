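"""Confusion-matrix metrics, ROC/AUC, cross-validation and robustness.

Metric conventions: sensitivity or specificity with a zero denominator is
reported as 0, and MCC with any zero factor under the square root is 0 —
reports never contain NaN. ACC + error rate = 1 and Q = (SN + SP) / 2 hold
exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import math

import numpy as np

from .classifiers import TrainConfig, fit_model
from .data import NEGATIVE, POSITIVE, LabeledDataset, RobustnessPair
from .descriptors import DescriptorConfig, FeatureMatrix, extract_all
from .tables import PropertyTableBundle


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (amyloid = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp, tn=self.tn + other.tn,
            fp=self.fp + other.fp, fn=self.fn + other.fn,
        )

    def table(self) -> str:
        """Counts in (TN, FP, FN, TP) layout for cross-checking reports."""
        return f"TN={self.tn} FP={self.fp} FN={self.fn} TP={self.tp}"


@dataclass(frozen=True)
class MetricsReport:
    """ACC, SN, SP, Q, MCC, error rate and (optionally) AUC."""

    acc: float
    sn: float
    sp: float
    q: float
    mcc: float
    error_rate: float
    auc: Optional[float] = None
    counts: Optional[ConfusionMatrix] = None

    def to_dict(self) -> dict:
        d = {
            "ACC": self.acc, "SN": self.sn, "SP": self.sp,
            "Q": self.q, "MCC": self.mcc, "ErrorRate": self.error_rate,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        if self.counts is not None:
            d.update(TP=self.counts.tp, TN=self.counts.tn,
                     FP=self.counts.fp, FN=self.counts.fn)
        return d


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Tally binary confusion counts (positive class = amyloid = 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not set(np.unique(arr)) <= {NEGATIVE, POSITIVE}:
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((y_true == POSITIVE) & (y_pred == POSITIVE)).sum()),
        tn=int(((y_true == NEGATIVE) & (y_pred == NEGATIVE)).sum()),
        fp=int(((y_true == NEGATIVE) & (y_pred == POSITIVE)).sum()),
        fn=int(((y_true == POSITIVE) & (y_pred == NEGATIVE)).sum()),
    )


def metrics(cm: ConfusionMatrix, auc: Optional[float] = None) -> MetricsReport:
    """The full metric set from confusion counts.

    ACC = (TP+TN)/N, SN = TP/(TP+FN), SP = TN/(TN+FP), Q = (SN+SP)/2,
    MCC = (TP·TN − FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    error rate = (FP+FN)/N.
    """
    if cm.total <= 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    sn = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else 0.0
    sp = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else 0.0
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = (
        (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom) if denom > 0 else 0.0
    )
    return MetricsReport(
        acc=acc, sn=sn, sp=sp, q=(sn + sp) / 2.0, mcc=mcc,
        error_rate=(cm.fp + cm.fn) / cm.total, auc=auc, counts=cm,
    )


def roc_curve_points(scores, y_true) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR) from a sweep over the distinct scores.

    Thresholds run from +inf (nothing predicted positive) down through
    every distinct score, so the curve starts at (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if scores.shape != y_true.shape:
        raise ValueError("scores and y_true must have equal length")
    n_pos = int((y_true == POSITIVE).sum())
    n_neg = int((y_true == NEGATIVE).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in y_true")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    is_pos = (y_true[order] == POSITIVE).astype(float)
    tp = np.cumsum(is_pos)
    fp = np.cumsum(1.0 - is_pos)
    # collapse tied scores: keep only the last index of each tie block
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return fpr, tpr


def roc_auc(scores, y_true) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve plus trapezoidal AUC.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half.
    """
    fpr, tpr = roc_curve_points(scores, y_true)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Stratified k-fold result: per-fold reports plus pooled counts."""

    k: int
    fold_reports: list[MetricsReport]
    pooled: MetricsReport


def stratified_folds(y, k: int, seed: int) -> list[np.ndarray]:
    """Index arrays of k stratified folds (sizes differ by at most 1)."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (POSITIVE, NEGATIVE):
        idx = np.flatnonzero(y == cls)
        if 0 < len(idx) < k:
            raise ValueError(f"class {cls} has fewer than k={k} samples")
        idx = rng.permutation(idx)
        for pos, sample in enumerate(idx):
            folds[pos % k].append(int(sample))
    return [np.array(sorted(f), dtype=int) for f in folds]


def kfold_cv(X: FeatureMatrix, config: TrainConfig, k: Optional[int] = None,
             seed: Optional[int] = None) -> CVResult:
    """Stratified k-fold cross-validation of the configured classifier.

    Per-fold metrics come from each validation fold; the pooled report is
    computed from the summed confusion counts, so every sample contributes
    exactly once.
    """
    k = k if k is not None else config.cv_k
    seed = seed if seed is not None else config.seed
    y = X.labels
    if y is None:
        raise ValueError("kfold_cv requires a labelled feature matrix")
    folds = stratified_folds(y, k, seed)
    all_idx = np.arange(len(y))
    reports = []
    pooled_cm = ConfusionMatrix(0, 0, 0, 0)
    pooled_scores = np.empty(len(y))
    for fold in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[fold] = False
        model = fit_model(X.values[train_mask], config, y=y[train_mask])
        pred = model.predict(X.values[fold])
        scores = model.decision_scores(X.values[fold])
        pooled_scores[fold] = scores
        cm = confusion(y[fold], pred)
        try:
            _, _, fold_auc = roc_auc(scores, y[fold])
        except ValueError:
            fold_auc = None
        reports.append(metrics(cm, auc=fold_auc))
        pooled_cm = pooled_cm + cm
    _, _, pooled_auc = roc_auc(pooled_scores, y)
    return CVResult(k=k, fold_reports=reports, pooled=metrics(pooled_cm, auc=pooled_auc))


# ---------------------------------------------------------------------------
# Robustness protocol


@dataclass
class RobustnessResult:
    """Per-pair validation/test reports and their ACC/SN/SP averages."""

    validation_reports: list[MetricsReport]
    test_reports: list[MetricsReport]

    def _avg(self, reports, attr) -> float:
        return float(np.mean([getattr(r, attr) for r in reports]))

    def averages(self) -> dict[str, float]:
        return {
            "validation_ACC": self._avg(self.validation_reports, "acc"),
            "validation_SN": self._avg(self.validation_reports, "sn"),
            "validation_SP": self._avg(self.validation_reports, "sp"),
            "test_ACC": self._avg(self.test_reports, "acc"),
            "test_SN": self._avg(self.test_reports, "sn"),
            "test_SP": self._avg(self.test_reports, "sp"),
        }


def robustness_run(
    pairs: Sequence[RobustnessPair],
    descriptor_config: Optional[DescriptorConfig] = None,
    train_config: Optional[TrainConfig] = None,
    tables: Optional[PropertyTableBundle] = None,
) -> RobustnessResult:
    """Retrain on every resampled pair, recomputing descriptors each time.

    For each pair the classifier is trained on the pair's training set and
    evaluated both on that training set (validation phase) and on the
    held-out test set; ACC/SN/SP are averaged over pairs.
    """
    if len(pairs) == 0:
        raise ValueError("robustness_run needs at least one pair")
    train_config = train_config or TrainConfig()
    val_reports, test_reports = [], []
    for pair in pairs:
        try:
            Xtr = extract_all(pair.train, descriptor_config, tables)
            Xte = extract_all(pair.test, descriptor_config, tables)
            model = fit_model(Xtr, train_config)
            for X, ds, sink in (
                (Xtr, pair.train, val_reports),
                (Xte, pair.test, test_reports),
            ):
                pred = model.predict(X.values)
                scores = model.decision_scores(X.values)
                cm = confusion(ds.labels, pred)
                _, _, auc = roc_auc(scores, ds.labels)
                sink.append(metrics(cm, auc=auc))
        except Exception as exc:
            raise RuntimeError(f"robustness pair {pair.index}: {exc}") from exc
    return RobustnessResult(validation_reports=val_reports, test_reports=test_reports)
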