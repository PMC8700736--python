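"""Quadratic-kernel SVM classification and the multiclass evaluation suite.

The classifier is a degree-2 polynomial ("quadratic") kernel SVM with box
constraint 1, features standardized by training-set statistics, one-vs-one
multiclass decomposition, and an automatic kernel scale.  Evaluation reports
a confusion matrix with accuracy, macro precision/recall/F1, Cohen's kappa
and the multiclass Matthews correlation coefficient, all on a 0-100 scale.
Pairwise per-feature Welch t-tests across class pairs provide a statistical
check that selected features actually separate the classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix,
    matthews_corrcoef,
    precision_recall_fscore_support,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import LabeledFeatureMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SVMSpec:
    """Hyperparameters of the quadratic SVM.

    ``kernel_scale="auto"`` maps to gamma = 1 / (p * mean feature variance)
    computed on the standardized training matrix (scikit-learn's "scale"),
    so the kernel is (x.z / (p * var) + 1)^2.
    """

    degree: int = 2
    box_constraint: float = 1.0
    standardize: bool = True
    kernel_scale: str = "auto"
    coef0: float = 1.0


def make_svm(spec: SVMSpec = SVMSpec()):
    """Build the (optionally standardizing) quadratic-SVM estimator."""
    gamma = "scale" if spec.kernel_scale == "auto" else float(spec.kernel_scale)
    svc = SVC(
        kernel="poly",
        degree=spec.degree,
        C=spec.box_constraint,
        gamma=gamma,
        coef0=spec.coef0,
        decision_function_shape="ovo",
    )
    if spec.standardize:
        # with_std leaves zero-variance features centered, not rescaled
        return make_pipeline(StandardScaler(), svc)
    return svc


def fit_predict_svm(train: LabeledFeatureMatrix, test: LabeledFeatureMatrix,
                    spec: SVMSpec = SVMSpec()) -> np.ndarray:
    """Fit the quadratic SVM on ``train`` and predict labels for ``test``."""
    if train.p != test.p:
        raise ValueError(
            f"train has {train.p} features but test has {test.p}"
        )
    zero_var = train.X.std(axis=0) == 0
    if spec.standardize and zero_var.any():
        log.info("leaving %d zero-variance feature(s) centered only",
                 int(zero_var.sum()))
    model = make_svm(spec)
    model.fit(train.X, train.y)
    return model.predict(test.X)


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = truth) and the six overall metrics.

    Metrics are percentages: accuracy, macro precision/recall/F1 in
    [0, 100]; Cohen's kappa and the Matthews correlation coefficient are
    coefficients in [-1, 1] reported x100 on the same scale.
    """

    labels: np.ndarray
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    cohen_kappa: float
    mcc: float
    per_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "labels": [str(c) for c in self.labels],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "cohen_kappa": self.cohen_kappa,
            "mcc": self.mcc,
            "per_class": {k: list(map(float, v))
                          for k, v in self.per_class.items()},
        }


def compute_report(truth, predicted) -> ClassificationReport:
    """Evaluate predictions against truth over the truth label universe.

    Predicted labels outside the truth's label set are an error: the
    classifier contract never invents classes.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape[0] != predicted.shape[0]:
        raise ValueError("truth and predicted must have equal length")
    if truth.shape[0] == 0:
        raise ValueError("no instances to evaluate")
    labels = np.unique(truth)
    unseen = np.setdiff1d(np.unique(predicted), labels)
    if unseen.size:
        raise ValueError(f"predicted labels not in truth universe: {unseen}")
    cm = confusion_matrix(truth, predicted, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, predicted, labels=labels, average=None, zero_division=0
    )
    return ClassificationReport(
        labels=labels,
        confusion=cm,
        accuracy=100.0 * np.trace(cm) / cm.sum(),
        precision=100.0 * prec.mean(),
        recall=100.0 * rec.mean(),
        f1=100.0 * f1.mean(),
        cohen_kappa=100.0 * cohen_kappa_score(truth, predicted, labels=labels),
        mcc=100.0 * matthews_corrcoef(truth, predicted),
        per_class={
            "precision": 100.0 * prec,
            "recall": 100.0 * rec,
            "f1": 100.0 * f1,
        },
    )


@dataclass
class TTestMatrix:
    """Per-feature Welch t-test p-values for every unordered class pair."""

    pairs: list
    p_values: np.ndarray          # (p features, n pairs)
    significant_counts: np.ndarray  # features with p < 0.05, per pair
    alpha: float = 0.05


def pairwise_feature_ttests(data: LabeledFeatureMatrix,
                            alpha: float = 0.05) -> TTestMatrix:
    """Welch two-sample t-tests of every feature for every class pair.

    Features with zero variance in both groups of a pair are reported with
    p = 1 (no evidence of separation).  Also counts, per pair, how many
    features reach p < alpha.
    """
    classes = data.classes
    for cls in classes:
        if (data.y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
    pairs = list(combinations(classes, 2))
    P = np.empty((data.p, len(pairs)))
    for j, (a, b) in enumerate(pairs):
        Xa, Xb = data.X[data.y == a], data.X[data.y == b]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(Xa, Xb, equal_var=False)
        pv = np.asarray(res.pvalue, dtype=float)
        degenerate = ~np.isfinite(pv)
        if degenerate.any():
            log.info("pair %r-%r: %d degenerate feature(s), p set to 1",
                     a, b, int(degenerate.sum()))
            pv[degenerate] = 1.0
        P[:, j] = pv
    return TTestMatrix(
        pairs=pairs,
        p_values=P,
        significant_counts=(P < alpha).sum(axis=0),
        alpha=alpha,
    )
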