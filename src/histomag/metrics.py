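"""Evaluation primitives: confusion matrix, class metrics, ROC/AUC,
stratified k-fold cross-validation and the paired t-test.

Malignant is the positive class throughout.  Rounding to the published-table
precision (3-decimal proportions, 1-decimal percents) happens only
at reporting, never inside a computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, HistomagError

POSITIVE = "malignant"
NEGATIVE = "benign"


def _as_binary(labels) -> np.ndarray:
    """Map benign/malignant (or 0/1) labels to {0, 1} with malignant = 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        out = arr.astype(int)
        if not np.isin(out, (0, 1)).all():
            raise ConfigError("integer labels must be 0 (benign) or 1 (malignant)")
        return out
    mapping = {NEGATIVE: 0, POSITIVE: 1}
    try:
        return np.array([mapping[str(v)] for v in arr])
    except KeyError as exc:
        raise ConfigError(f"unknown label {exc.args[0]!r}") from exc


@dataclass
class ConfusionMatrix:
    """2x2 counts with benign = negative, malignant = positive."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.tn, self.fp], [self.fn, self.tp]],
            index=[f"true_{NEGATIVE}", f"true_{POSITIVE}"],
            columns=[f"pred_{NEGATIVE}", f"pred_{POSITIVE}"],
        )


def confusion(y_true, y_pred) -> ConfusionMatrix:
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    if len(t) != len(p):
        raise ConfigError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tp=int(np.sum((t == 1) & (p == 1))),
    )


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1 plus overall accuracy.

    ``degenerate`` flags any zero-denominator case, where the convention
    value 0 is reported.
    """

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = {
            cls: {"precision": self.precision[cls], "recall": self.recall[cls],
                  "f1": self.f1[cls]}
            for cls in (NEGATIVE, POSITIVE)
        }
        frame = pd.DataFrame(rows).T
        frame["accuracy"] = self.accuracy
        return frame


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean, with the f1 = 0 convention when P + R = 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    if cm.total == 0:
        raise ConfigError("confusion matrix is empty")
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = {POSITIVE: ratio(cm.tp, cm.tp + cm.fp),
                 NEGATIVE: ratio(cm.tn, cm.tn + cm.fn)}
    recall = {POSITIVE: ratio(cm.tp, cm.tp + cm.fn),
              NEGATIVE: ratio(cm.tn, cm.tn + cm.fp)}
    f1 = {cls: f1_score(precision[cls], recall[cls]) for cls in precision}
    accuracy = (cm.tp + cm.tn) / cm.total
    return ClassMetrics(precision=precision, recall=recall, f1=f1,
                        accuracy=accuracy, degenerate=degenerate)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc(y_true, malignant_scores) -> RocCurve:
    """ROC by descending-threshold sweep; tied scores form a single step;
    AUC by the trapezoid rule."""
    t = _as_binary(y_true)
    scores = np.asarray(malignant_scores, float)
    if not np.all(np.isfinite(scores)):
        raise ConfigError("scores must be finite")
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise HistomagError("ROC requires both classes present")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_true = t[order]
    # indices where the score changes: one ROC point per distinct score
    distinct = np.where(np.diff(sorted_scores))[0]
    cut = np.r_[distinct, len(t) - 1]
    tps = np.cumsum(sorted_true)[cut]
    fps = (cut + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[cut]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

CV_COLUMNS = ("train", "val", "test", "precision", "f1")


@dataclass
class CVReport:
    """Per-fold metric table (percent scale) with mean/std summary rows."""

    folds: pd.DataFrame  # index = fold number, columns = CV_COLUMNS
    k: int = 5

    @property
    def mean(self) -> pd.Series:
        return self.folds.mean()

    @property
    def std(self) -> pd.Series:
        return self.folds.std(ddof=1)

    def mean_percent(self, column: str, decimals: int = 1) -> float:
        """Summary mean at the usual 1-decimal percent reporting precision."""
        return round(float(self.folds[column].mean()), decimals)

    @classmethod
    def from_columns(cls, columns: dict[str, list[float]]) -> "CVReport":
        frame = pd.DataFrame(columns)
        frame.index = np.arange(1, len(frame) + 1)
        return cls(folds=frame, k=len(frame))

    def to_frame(self) -> pd.DataFrame:
        out = self.folds.copy()
        out.loc["mean"] = self.mean
        out.loc["std"] = self.std
        return out


def kfold_cv(
    images: np.ndarray,
    labels: np.ndarray,
    model_factory,
    tcfg,
    k: int = 5,
    seed: int = 42,
    val_fraction: float = 0.15,
) -> CVReport:
    """Stratified k-fold cross-validation of a trainable classifier.

    Each fold trains on the other k-1 folds (with an inner stratified
    validation carve-out) and tests on the held-out fold.
    ``model_factory()`` must return a fresh model accepted by
    :func:`histomag.nn.vit.train`.  Metrics are reported on the percent
    scale, with precision/F1 for the malignant class.
    """
    from sklearn.model_selection import StratifiedKFold, train_test_split

    from .nn.vit import evaluate, train as train_model

    y = _as_binary(labels)
    if k < 2:
        raise ConfigError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise HistomagError(f"smallest class has {counts.min()} samples; cannot build {k} folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(images, y), start=1):
        tr_idx, val_idx = train_test_split(
            train_idx, test_size=val_fraction, stratify=y[train_idx],
            random_state=seed + fold,
        )
        model = model_factory()
        train_model(model, (images[tr_idx], y[tr_idx]), (images[val_idx], y[val_idx]), tcfg)
        _, train_acc = evaluate(model, images[tr_idx], y[tr_idx])
        _, val_acc = evaluate(model, images[val_idx], y[val_idx])
        pred = model.predict(images[test_idx])
        cm = confusion(y[test_idx], pred)
        m = class_metrics(cm)
        rows.append({
            "train": 100.0 * train_acc,
            "val": 100.0 * val_acc,
            "test": 100.0 * m.accuracy,
            "precision": 100.0 * m.precision[POSITIVE],
            "f1": 100.0 * m.f1[POSITIVE],
        })
    return CVReport(folds=pd.DataFrame(rows, index=np.arange(1, k + 1)), k=k)


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

@dataclass
class PairedTTestResult:
    mean_difference: float
    t_value: float
    p_value: float
    degrees_of_freedom: int
    degenerate: bool = False


def paired_ttest(a, b) -> PairedTTestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), sample sd.

    Zero-variance differences yield a degenerate-result flag instead of a
    division by zero.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("a and b must be 1-D with equal length")
    n = len(a)
    if n < 2:
        raise ConfigError("need at least 2 paired scores")
    d = a - b
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        return PairedTTestResult(mean_difference=mean_d, t_value=np.nan,
                                 p_value=1.0, degrees_of_freedom=df, degenerate=True)
    t_value = mean_d / (sd / np.sqrt(n))
    p_value = float(2.0 * stats.t.sf(abs(t_value), df))
    return PairedTTestResult(mean_difference=mean_d, t_value=float(t_value),
                             p_value=p_value, degrees_of_freedom=df)
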