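"""Brain-age-gap (BAG) based Alzheimer's detection.

BAG = predicted brain age - chronological age.  Because the regressor is
trained on cognitively normal subjects, accelerated aging in AD shows up
as a positive BAG shift, and the scalar BAG alone carries enough signal to
separate AD from CN.  Four binary classifiers — logistic regression, SVM,
AdaBoost and XGBoost — are fitted on the 1-D BAG feature and combined by
majority voting; a 2-2 tie is broken by the mean of the four predicted AD
probabilities against 0.5, and the ensemble's ROC score is that mean
probability.

The report metrics come straight from the confusion counts:
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean,
accuracy = (TP+TN)/n; the ROC is a threshold sweep over the scores with
trapezoid-rule AUC.  AD is the positive class throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

logger = logging.getLogger("brainage")

POSITIVE = "AD"


@dataclass
class AgePrediction:
    """One scan's chronological age, predicted brain age and diagnosis."""

    scan_id: str
    chronological_age: float
    brain_age: float
    diagnosis: str

    @property
    def bag(self) -> float:
        return self.brain_age - self.chronological_age


def compute_bag(predictions: Sequence[tuple[float, float]] | np.ndarray) -> np.ndarray:
    """Elementwise brain_age - chronological_age, order preserved.

    ``predictions`` is a sequence of (chronological, brain_age) pairs.
    """
    arr = np.asarray(predictions, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (n, 2) pairs of ages, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("ages must be finite")
    return arr[:, 1] - arr[:, 0]


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleModel:
    """Four fitted base classifiers over the 1-D BAG feature."""

    classifiers: dict[str, object]
    seed: int

    def base_probabilities(self, bag: np.ndarray) -> dict[str, np.ndarray]:
        x = np.asarray(bag, dtype=float).reshape(-1, 1)
        return {name: clf.predict_proba(x)[:, 1] for name, clf in self.classifiers.items()}


def fit_classifiers(bag: np.ndarray, labels: Sequence[str], seed: int = 0) -> EnsembleModel:
    """Fit the four base classifiers on training BAG values; deterministic per seed."""
    bag = np.asarray(bag, dtype=float).reshape(-1, 1)
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels must contain both CN and AD")
    classifiers = {
        "logistic_regression": LogisticRegression(random_state=seed),
        "svm": SVC(probability=True, random_state=seed),
        "adaboost": AdaBoostClassifier(random_state=seed),
        "xgboost": XGBClassifier(
            n_estimators=50, max_depth=2, random_state=seed, n_jobs=1,
            eval_metric="logloss",
        ),
    }
    for clf in classifiers.values():
        clf.fit(bag, y)
    return EnsembleModel(classifiers=classifiers, seed=seed)


def ensemble_predict(model: EnsembleModel, bag: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote of the four base classifiers.

    Returns (labels in {"CN","AD"}, ensemble AD probabilities).  A 2-2 vote
    tie goes to AD iff the mean of the four predicted AD probabilities
    exceeds 0.5; the mean probability is also the ensemble's ROC score.
    """
    probs = model.base_probabilities(bag)
    votes = np.stack([(p >= 0.5).astype(int) for p in probs.values()])
    mean_prob = np.mean(np.stack(list(probs.values())), axis=0)
    tally = votes.sum(axis=0)
    k = votes.shape[0]
    decision = np.where(tally * 2 == k, mean_prob > 0.5, tally * 2 > k)
    labels = np.where(decision, POSITIVE, "CN")
    return labels, mean_prob


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ClassifierReport:
    """Confusion counts, derived metrics and the ROC curve (AD positive)."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    accuracy: float
    roc: list[tuple[float, float]]
    auc: float
    per_classifier: dict[str, "ClassifierReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy,
            "roc": [list(p) for p in self.roc], "auc": self.auc,
        }
        if self.per_classifier:
            d["per_classifier"] = {k: v.to_dict() for k, v in self.per_classifier.items()}
        return d


def roc_points(truth: np.ndarray, scores: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) by sweeping a threshold over the scores, descending."""
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    pos = int((y == 1).sum())
    neg = len(y) - pos
    order = np.argsort(-s, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    prev = None
    for i in order:
        if prev is not None and s[i] != prev:
            points.append((fp / neg if neg else 0.0, tp / pos if pos else 0.0))
        if y[i] == 1:
            tp += 1
        else:
            fp += 1
        prev = s[i]
    points.append((fp / neg if neg else 0.0, tp / pos if pos else 0.0))
    return points


def classification_metrics(
    truth: Sequence[str] | np.ndarray,
    predicted: Sequence[str] | np.ndarray,
    probabilities: Optional[np.ndarray] = None,
) -> ClassifierReport:
    """Confusion-count metrics plus ROC/AUC; AD is the positive class."""
    t = np.asarray([1 if l == POSITIVE else 0 for l in np.asarray(truth)])
    p = np.asarray([1 if l == POSITIVE else 0 for l in np.asarray(predicted)])
    if len(t) != len(p):
        raise ValueError("truth and predicted must have equal length")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if precision + recall > 0 and np.isfinite(precision) and np.isfinite(recall):
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
    accuracy = (tp + tn) / len(t)

    roc: list[tuple[float, float]] = []
    auc = float("nan")
    if probabilities is not None:
        roc = roc_points(t, probabilities)
        fpr = np.array([q[0] for q in roc])
        tpr = np.array([q[1] for q in roc])
        auc = float(np.trapezoid(tpr, fpr))
    return ClassifierReport(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                            recall=recall, f1=f1, accuracy=accuracy, roc=roc, auc=auc)


# ---------------------------------------------------------------------------
# the end-to-end detection procedure


def stratified_split(labels: Sequence[str], test_fraction: float = 0.15, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; returns (train indices, test indices)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test].tolist())
        train_idx.extend(idx[n_test:].tolist())
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def classify_ad(
    predictions: Sequence[AgePrediction],
    test_fraction: float = 0.15,
    seed: int = 0,
) -> ClassifierReport:
    """Full BAG-biomarker detection: split, fit the four classifiers, report.

    The BAG samples are split 85/15 stratified by diagnosis; the ensemble
    and each base classifier are evaluated on the held-out 15%.
    """
    bags = np.array([p.bag for p in predictions])
    labels = np.array([p.diagnosis for p in predictions])
    tr, te = stratified_split(labels, test_fraction, seed)
    model = fit_classifiers(bags[tr], labels[tr], seed=seed)
    pred_labels, mean_prob = ensemble_predict(model, bags[te])
    report = classification_metrics(labels[te], pred_labels, mean_prob)
    for name, prob in model.base_probabilities(bags[te]).items():
        base_pred = np.where(prob >= 0.5, POSITIVE, "CN")
        report.per_classifier[name] = classification_metrics(labels[te], base_pred, prob)
    return report
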