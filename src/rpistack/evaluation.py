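"""Binary-classification evaluation: confusion-count metrics, ROC/AUC,
and stratified five-fold cross-validation of the full pipeline.

Point metrics are computed from confusion counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    MCC         = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with any zero denominator factor mapping the statistic to 0.  AUC is
the area under the ROC curve, equal to the midrank-normalized
Mann–Whitney U statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve, auc as _trapezoid_auc
from sklearn.model_selection import StratifiedKFold

from .io_formats import PairTable, ValidationError


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"confusion count {name} = {v} invalid")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class PointMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "mcc": self.mcc,
        }


def compute_metrics(c: ConfusionCounts) -> PointMetrics:
    """Point metrics from confusion counts; zero denominators map to 0."""
    if c.total == 0:
        raise ValidationError("all confusion counts are zero")

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else 0.0

    mcc_den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_den) if mcc_den > 0 else 0.0
    )
    return PointMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        mcc=mcc,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC curve and AUC; ties handled by midrank (trapezoidal area).

    Returns ``(auc, fpr, tpr, thresholds)``; raises if only one class is
    present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValidationError("ROC/AUC undefined with a single class")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr, thresholds


@dataclass
class FoldResult:
    metrics: PointMetrics
    auc: float
    n: int

    def to_dict(self) -> dict:
        out = self.metrics.to_dict()
        out["auc"] = self.auc
        out["n"] = self.n
        return out


@dataclass
class MetricsReport:
    """Per-fold metrics plus their mean and the pooled-prediction metrics
    (both summaries are reported because published cross-validation
    tables rarely say which convention they use)."""

    folds: list[FoldResult]
    pooled: FoldResult | None = None
    extra: dict = field(default_factory=dict)
    # pooled out-of-fold scores/labels, kept for ROC export; not serialized
    pooled_scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)

    def mean(self) -> dict:
        keys = ["accuracy", "sensitivity", "specificity", "precision", "mcc", "auc"]
        return {
            k: float(np.mean([f.to_dict()[k] for f in self.folds])) for k in keys
        }

    def to_dict(self) -> dict:
        out = {
            "folds": [f.to_dict() for f in self.folds],
            "mean": self.mean(),
        }
        if self.pooled is not None:
            out["pooled"] = self.pooled.to_dict()
        if self.extra:
            out["extra"] = self.extra
        return out


def metrics_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> FoldResult:
    """Threshold scores (ties -> positive), count, and compute metrics + AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    preds = (scores >= threshold).astype(int)
    point = compute_metrics(confusion_counts(labels, preds))
    auc_val, _, _, _ = roc_auc(scores, labels)
    return FoldResult(metrics=point, auc=auc_val, n=labels.size)


def cross_validate(
    pairs: PairTable,
    protein_features: pd.DataFrame,
    rna_features: pd.DataFrame,
    sae_config=None,
    n_trees: int = 500,
    folds: int = 5,
    seed: int = 0,
    base_models: tuple[str, ...] | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the stacked pipeline.

    Every fitted component (feature scaler, auto-encoder, random
    forests, level-1 logistic combiner) is trained inside each training
    fold only.  Pair rows are canonicalized (sorted by ids) before
    folding so the report does not depend on input row order.
    """
    from .ensemble import assemble_pair_features, fit_stacked_ensemble

    frame = pairs.frame.sort_values(["protein_id", "rna_id"], kind="mergesort")
    frame = frame.reset_index(drop=True)
    canonical = PairTable(frame=frame)
    X, y = assemble_pair_features(canonical, protein_features, rna_features)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"need at least {folds} samples per class for {folds}-fold "
            f"stratified CV; got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    fold_results: list[FoldResult] = []
    pooled_scores = np.zeros(len(y))
    seeds = np.random.SeedSequence(seed).generate_state(folds) % (2**31)
    for i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        ensemble, _ = fit_stacked_ensemble(
            X[train_idx],
            y[train_idx],
            seed=int(seeds[i]),
            sae_config=sae_config,
            n_trees=n_trees,
            base_models=base_models,
        )
        scores = ensemble.predict_proba(X[test_idx])
        pooled_scores[test_idx] = scores
        fold_results.append(metrics_from_scores(scores, y[test_idx]))
    pooled = metrics_from_scores(pooled_scores, y)
    return MetricsReport(
        folds=fold_results, pooled=pooled, pooled_scores=pooled_scores, labels=y
    )
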