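"""Leave-one-out SVM classification, ROC, and permutation significance.

The classifier is a support-vector machine (linear kernel, C = 1 by default)
trained per fold on features selected from the training subjects only —
either that fold's own filter output (``per_fold``) or a stable set
recomputed from inner leave-one-out folds of the training subjects
(``stable``; a deliberately leaky variant reusing one global stable set is
available as ``stable_leaky`` for comparison).  Features are standardized
with training-fold statistics.  Significance of the real-label accuracy is
assessed by re-running the whole selection + classification pipeline under
label shuffles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import SelectionParams, fold_subsets, select_features, stabilize

__all__ = [
    "ClassificationReport",
    "loocv_classify",
    "roc_points",
    "permutation_test_accuracy",
    "replicate_classify",
]

log = logging.getLogger(__name__)


@dataclass
class ClassificationReport:
    """Confusion-count summary of a patients-vs-controls classifier.

    sensitivity = correct patients / all patients,
    specificity = correct controls / all controls,
    accuracy    = all correct / all subjects.
    """

    correct_patients: int
    total_patients: int
    correct_controls: int
    total_controls: int
    auc: float | None = None
    perm_p: float | None = None

    @classmethod
    def from_counts(cls, correct_patients, total_patients,
                    correct_controls, total_controls, **kw):
        return cls(int(correct_patients), int(total_patients),
                   int(correct_controls), int(total_controls), **kw)

    @property
    def sensitivity(self) -> float:
        return self.correct_patients / self.total_patients

    @property
    def specificity(self) -> float:
        return self.correct_controls / self.total_controls

    @property
    def accuracy(self) -> float:
        return (self.correct_patients + self.correct_controls) / (
            self.total_patients + self.total_controls
        )

    def to_dict(self) -> dict:
        d = {
            "correct_patients": self.correct_patients,
            "total_patients": self.total_patients,
            "correct_controls": self.correct_controls,
            "total_controls": self.total_controls,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.perm_p is not None:
            d["perm_p"] = self.perm_p
        return d


def _coerce(features, labels):
    import pandas as pd

    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        labels = labels == "patient"
    return x, labels.astype(bool)


def _fit_predict(x_tr, y_tr, x_te, kernel, c):
    scaler = StandardScaler().fit(x_tr)
    clf = SVC(kernel=kernel, C=c)
    clf.fit(scaler.transform(x_tr), y_tr.astype(int))
    z = clf.decision_function(scaler.transform(x_te))
    return z, z > 0


def loocv_classify(
    features,
    labels,
    qol,
    params: SelectionParams,
    feature_mode: str = "per_fold",
    tau: float = 0.90,
    kernel: str = "linear",
    C: float = 1.0,
    subsets=None,
    return_decisions: bool = False,
):
    """Leave-one-out classification with nested, training-only selection.

    ``subsets`` may carry precomputed per-fold selections (as returned by
    :func:`dysconnect.selection.fold_subsets` on the same data and params)
    to avoid recomputing them in sweeps.  Folds whose feature set comes out
    empty fall back to the training majority class (logged).
    """
    x, y = _coerce(features, labels)
    qol = np.asarray(qol, dtype=float)
    n = x.shape[0]
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("need at least 3 subjects per class")
    if feature_mode not in ("per_fold", "stable", "stable_leaky"):
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    if feature_mode == "per_fold" and subsets is None:
        subsets = fold_subsets(x, y, qol, params)
    leaky_idx = None
    if feature_mode == "stable_leaky":
        # information leak by construction: stable set from ALL subjects
        leaky_idx = stabilize(fold_subsets(x, y, qol, params), tau).indices
    decisions = np.zeros(n)
    pred = np.zeros(n, dtype=bool)
    for k in range(n):
        tr = np.ones(n, dtype=bool)
        tr[k] = False
        if feature_mode == "per_fold":
            idx = np.asarray(subsets[k].indices, dtype=int)
        elif feature_mode == "stable":
            inner_params = SelectionParams(params.p_level, params.n_permutations,
                                           params.corr_alpha, params.seed)
            inner = fold_subsets(x[tr], y[tr], qol[tr], inner_params)
            idx = stabilize(inner, tau).indices
        else:
            idx = leaky_idx
        if idx is None or len(idx) == 0:
            maj = y[tr].sum() > (~y[tr]).sum()
            pred[k] = maj
            decisions[k] = 0.0
            log.info("fold %d: empty feature set, majority-class fallback", k)
            continue
        z, p = _fit_predict(x[tr][:, idx], y[tr], x[k][None, idx], kernel, C)
        decisions[k] = z[0]
        pred[k] = p[0]
        log.debug("fold %d: %d features, predicted %s", k, len(idx), pred[k])
    report = ClassificationReport.from_counts(
        (pred & y).sum(), y.sum(), (~pred & ~y).sum(), (~y).sum()
    )
    try:
        report.auc = float(metrics.roc_auc_score(y.astype(int), decisions))
    except ValueError:
        report.auc = None
    if return_decisions:
        return report, decisions
    return report


def roc_points(decision_values, labels):
    """ROC curve (fpr, tpr, thresholds) and AUC over held-out decision values."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        labels = labels == "patient"
    labels = labels.astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = metrics.roc_curve(labels, np.asarray(decision_values, float))
    return fpr, tpr, thr, float(metrics.auc(fpr, tpr))


def permutation_test_accuracy(
    features,
    labels,
    qol,
    params: SelectionParams,
    n_shuffles: int = 1000,
    seed: int = 0,
    feature_mode: str = "per_fold",
    tau: float = 0.90,
    kernel: str = "linear",
    C: float = 1.0,
):
    """Label-shuffle significance of the LOOCV accuracy.

    The full pipeline (fold-wise selection + SVM) is re-run per shuffle;
    perm_p = (1 + #{null accuracy >= real}) / (1 + n_shuffles).  Returns
    (report with perm_p set, null accuracy array).
    """
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives a coarse null",
                      RuntimeWarning, stacklevel=2)
    x, y = _coerce(features, labels)
    qol = np.asarray(qol, dtype=float)
    report = loocv_classify(x, y, qol, params, feature_mode, tau, kernel, C)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F]))
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(y))
        null[s] = loocv_classify(
            x, y[perm], qol, params, feature_mode, tau, kernel, C
        ).accuracy
    report.perm_p = float((1.0 + np.sum(null >= report.accuracy)) / (1.0 + n_shuffles))
    return report, null


def replicate_classify(
    train_features,
    train_labels,
    stable_indices,
    test_features,
    test_labels,
    kernel: str = "linear",
    C: float = 1.0,
) -> ClassificationReport:
    """Fit once on the full training cohort (stable features only) and
    score an independent replication cohort."""
    x_tr, y_tr = _coerce(train_features, train_labels)
    x_te, y_te = _coerce(test_features, test_labels)
    idx = np.asarray(
        stable_indices.indices if hasattr(stable_indices, "indices") else stable_indices,
        dtype=int,
    )
    if idx.size == 0:
        raise ValueError("stable feature set is empty")
    if idx.max() >= x_te.shape[1] or idx.max() >= x_tr.shape[1]:
        raise ValueError("stable feature index absent from the feature vectors")
    z, pred = _fit_predict(x_tr[:, idx], y_tr, x_te[:, idx], kernel, C)
    report = ClassificationReport.from_counts(
        (pred & y_te).sum(), y_te.sum(), (~pred & ~y_te).sum(), (~y_te).sum()
    )
    try:
        report.auc = float(metrics.roc_auc_score(y_te.astype(int), z))
    except ValueError:
        report.auc = None
    return report
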