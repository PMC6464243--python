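"""Metrics, ROC/PR curves, cross-validation and candidate ranking.

Confusion-matrix metrics follow the standard definitions: accuracy
(TP+TN)/total, sensitivity TP/(TP+FN), precision TP/(TP+FP) and the
Matthews correlation coefficient; any metric whose denominator is zero
is reported as 0 with a flag rather than NaN. AUC is the trapezoidal
area under the ROC curve over all distinct score thresholds, which
coincides with the tie-corrected pair-counting (Mann-Whitney) statistic.

Cross-validation is stratified and seeded: folds are disjoint, within
one row of equal size, and every row is tested exactly once; confusion
metrics use the 0.5 probability threshold. Candidate ranking scores
every (disease, miRNA) pair for a query disease and returns the top N by
probability, ties broken by miRNA name, with known positives flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, DataError, UnknownEntityError
from .fusion import FeatureTable, build_feature_vector
from .io_formats import AssociationSet, NamedMatrix
from .lmt import LMTClassifier

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "mcc", "auc")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_scores(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (labels == 1))),
        tn=int(np.sum((pred == 0) & (labels == 0))),
        fp=int(np.sum((pred == 1) & (labels == 0))),
        fn=int(np.sum((pred == 0) & (labels == 1))),
    )


def metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, precision and MCC from confusion counts.

    Returns a dict that also carries ``zero_denominator`` flags naming
    the metrics whose denominator vanished (each reported as 0).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise DataError("empty confusion matrix")
    flags = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / counts.total
    sensitivity = safe(tp, tp + fn, "sensitivity")
    precision = safe(tp, tp + fp, "precision")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(tp * tn - fp * fn, mcc_den, "mcc")
    return {"accuracy": accuracy, "sensitivity": sensitivity,
            "precision": precision, "mcc": mcc,
            "zero_denominator": flags}


def roc_auc(scores, labels) -> float:
    """Trapezoidal AUC over all distinct thresholds (errors if one class)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise DataError("AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return float(_trapezoid_auc(fpr, tpr))


def roc_points(scores, labels) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int),
                              np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_curve(scores, labels) -> pd.DataFrame:
    prec, rec, thr = precision_recall_curve(np.asarray(labels).astype(int),
                                            np.asarray(scores, dtype=float))
    return pd.DataFrame({"recall": rec, "precision": prec,
                         "threshold": np.append(thr, np.nan)})


@dataclass
class MetricsReport:
    """Per-fold metrics plus their mean and standard deviation."""

    per_fold: list[dict]
    mean: dict = field(init=False)
    std: dict = field(init=False)

    def __post_init__(self) -> None:
        self.mean = {m: float(np.mean([f[m] for f in self.per_fold]))
                     for m in METRIC_NAMES}
        self.std = {m: float(np.std([f[m] for f in self.per_fold]))
                    for m in METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        rows = [{**{"fold": i + 1}, **{m: f[m] for m in METRIC_NAMES}}
                for i, f in enumerate(self.per_fold)]
        rows.append({"fold": "average",
                     **{m: self.mean[m] for m in METRIC_NAMES}})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        """Report layout: one row per fold, then an average +/- std row."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("test_set\t" + "\t".join(METRIC_NAMES) + "\n")
            for i, f in enumerate(self.per_fold, 1):
                fh.write(str(i) + "\t" +
                         "\t".join(f"{f[m]:.4f}" for m in METRIC_NAMES) + "\n")
            fh.write("average\t" + "\t".join(
                f"{self.mean[m]:.4f}+/-{self.std[m]:.4f}"
                for m in METRIC_NAMES) + "\n")


def _clone_classifier(classifier):
    if isinstance(classifier, LMTClassifier):
        return LMTClassifier(classifier.config)
    return clone(classifier)


def cross_validate(table: FeatureTable, classifier, k: int = 5,
                   seed: int = 0) -> MetricsReport:
    """Seeded stratified k-fold CV of any fit/predict_proba classifier.

    Per-fold confusion metrics are taken at probability threshold 0.5;
    each row lands in exactly one test fold.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    y = np.asarray(table.labels).astype(int)
    X = table.features
    if np.bincount(y, minlength=2).min() < k:
        raise DataError("a class has fewer rows than folds; "
                        "use more data or fewer folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y), 1):
        if len(np.unique(y[train_idx])) < 2:
            raise DataError(f"training fold {fold} lacks a class; "
                            "stratification failed")
        clf = _clone_classifier(classifier)
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        fold_metrics = metrics(confusion_from_scores(scores, y[test_idx]))
        fold_metrics["auc"] = roc_auc(scores, y[test_idx])
        fold_metrics["n_test"] = len(test_idx)
        per_fold.append(fold_metrics)
    return MetricsReport(per_fold=per_fold)


def rank_candidates(
    model,
    disease: str,
    assoc: AssociationSet,
    dsim: NamedMatrix,
    rsim: NamedMatrix,
    rseq: NamedMatrix,
    n: int = 30,
    mode: str = "full",
    include_known: bool = True,
) -> pd.DataFrame:
    """Top-N miRNA candidates for one disease by predicted probability.

    The model must expose predict_proba; known positives are flagged in
    the output and can be excluded. Ties are broken by miRNA name.
    """
    di = assoc.disease_index(disease)  # raises UnknownEntityError if absent
    rows = []
    feats = np.stack([
        build_feature_vector(disease, m, dsim, rsim, rseq, mode=mode)
        for m in assoc.mirnas
    ])
    probs = model.predict_proba(feats)
    if probs.ndim == 2:
        probs = probs[:, 1]
    for j, m in enumerate(assoc.mirnas):
        known = bool(assoc.ad[di, j])
        if known and not include_known:
            continue
        rows.append({"disease": disease, "mirna": m,
                     "score": float(probs[j]), "known": known})
    df = pd.DataFrame(rows).sort_values(
        ["score", "mirna"], ascending=[False, True]).reset_index(drop=True)
    return df.head(n)
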