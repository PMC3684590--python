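"""Model/Results front end for the whole discrimination analysis.

`ConnectivityDiscrimination` is constructed from a subject table and a
per-subject edge-feature matrix (statsmodels-style: data in, `fit()` out).
`fit()` runs the fold-wise two-filter selection, overlap-threshold
stabilization and leave-one-out SVM classification and returns a
`DiscriminationResults` carrying the confusion counts, ROC/AUC, stable
feature sets and fold subsets, with `summary()`, `predict()` (replication
cohorts), `severity()` (CSI stage) and `plot_roc()` hanging off it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from . import network as _network
from . import severity as _severity
from .selection import SelectionParams, StableFeatureSet, fold_subsets, stabilize

__all__ = ["ConnectivityDiscrimination", "DiscriminationResults", "SeverityResults"]


class ConnectivityDiscrimination:
    """Case-control discrimination model over vectorized connectivity features.

    Parameters
    ----------
    features : DataFrame or array, subjects x edges (Fisher-z values)
    subjects : DataFrame with columns subject_id, group, ndi_qol and
        (optionally) the other clinical scores; row order must match
        ``features``.
    atlas : optional ROI atlas table (roi_id, x_mm, y_mm, z_mm, system)
        used by the network report.
    """

    def __init__(self, features, subjects: pd.DataFrame, atlas: pd.DataFrame | None = None):
        self.features = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
            else np.asarray(features, dtype=float)
        if len(subjects) != self.features.shape[0]:
            raise ValueError("subject table and feature matrix disagree on n")
        self.subjects = subjects.reset_index(drop=True)
        self.labels = (self.subjects["group"] == "patient").to_numpy()
        self.qol = self.subjects["ndi_qol"].to_numpy(dtype=float)
        self.atlas = atlas

    @classmethod
    def from_dataframes(cls, subjects: pd.DataFrame, features: pd.DataFrame,
                        atlas: pd.DataFrame | None = None) -> "ConnectivityDiscrimination":
        """Align a feature DataFrame (indexed by subject_id) with a subject table."""
        feat = features.loc[subjects["subject_id"].to_numpy()]
        return cls(feat, subjects, atlas)

    def fit(
        self,
        p_level: float = 0.01,
        n_permutations: int = 1000,
        corr_alpha: float = 0.05,
        tau: float | tuple[float, ...] = (1.0, 0.95, 0.90, 0.85),
        feature_mode: str = "per_fold",
        seed: int = 0,
        kernel: str = "linear",
        C: float = 1.0,
    ) -> "DiscriminationResults":
        params = SelectionParams(p_level=p_level, n_permutations=n_permutations,
                                 corr_alpha=corr_alpha, seed=seed)
        taus = (tau,) if np.isscalar(tau) else tuple(tau)
        subsets = fold_subsets(self.features, self.labels, self.qol, params)
        stable = {t: stabilize(subsets, t) for t in taus}
        report, decisions = _classify.loocv_classify(
            self.features, self.labels, self.qol, params,
            feature_mode=feature_mode, tau=taus[0], kernel=kernel, C=C,
            subsets=subsets if feature_mode == "per_fold" else None,
            return_decisions=True,
        )
        return DiscriminationResults(
            model=self, params=params, feature_mode=feature_mode,
            kernel=kernel, C=C, report=report, decisions=decisions,
            fold_subsets=subsets, stable_sets=stable,
        )


@dataclass
class DiscriminationResults:
    """Fitted discrimination analysis: confusion counts, ROC, stable sets."""

    model: ConnectivityDiscrimination
    params: SelectionParams
    feature_mode: str
    kernel: str
    C: float
    report: _classify.ClassificationReport
    decisions: np.ndarray
    fold_subsets: list
    stable_sets: dict[float, StableFeatureSet] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def auc(self) -> float | None:
        return self.report.auc

    def stable(self, tau: float) -> StableFeatureSet:
        if tau not in self.stable_sets:
            self.stable_sets[tau] = stabilize(self.fold_subsets, tau)
        return self.stable_sets[tau]

    def roc(self):
        return _classify.roc_points(self.decisions, self.model.labels)

    def predict(self, test_features, test_subjects: pd.DataFrame,
                tau: float = 0.90) -> _classify.ClassificationReport:
        """Classify an independent replication cohort with the stable set."""
        y = (test_subjects["group"] == "patient").to_numpy()
        return _classify.replicate_classify(
            self.model.features, self.model.labels, self.stable(tau),
            test_features, y, kernel=self.kernel, C=self.C,
        )

    def severity(self, tau: float = 0.90) -> "SeverityResults":
        """CSI stage: leave-one-out QoL prediction over patients, normalized."""
        m = self.model
        pats = m.subjects[m.labels].reset_index(drop=True)
        x = m.features[m.labels]
        pred = _severity.predict_scores(x, pats["ndi_qol"].to_numpy(dtype=float),
                                        self.stable(tau), kernel=self.kernel, C=self.C)
        table = _severity.compute_csi(pred, pats)
        corr = _severity.csi_correlations(table)
        return SeverityResults(table=table, correlations=corr, tau=tau)

    def network_report(self, tau: float = 0.90, atlas: pd.DataFrame | None = None) -> dict:
        """Annotated stable edges, node weights, length test, system tallies."""
        atlas = atlas if atlas is not None else self.model.atlas
        if atlas is None:
            raise ValueError("an ROI atlas is required for the network report")
        m = self.model
        ann = _network.annotate_edges(
            self.stable(tau), atlas, m.features, m.qol,
            m.subjects["age_years"].to_numpy(dtype=float),
        )
        n_rois = int(atlas["roi_id"].max()) + 1
        return {
            "annotations": ann,
            "node_weights": _network.node_weights(self.stable(tau), n_rois),
            "length_test": _network.sign_split_length_test(ann),
            "system_proportions": _network.system_proportions(ann),
        }

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        fpr, tpr, _, auc = self.roc()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax

    def summary(self) -> str:
        r = self.report
        lines = [
            "Connectivity discrimination (leave-one-out SVM)",
            "=" * 52,
            f"subjects            {r.total_patients} patients / {r.total_controls} controls",
            f"selection           P = {self.params.p_level}, "
            f"{self.params.n_permutations} permutations, "
            f"corr alpha = {self.params.corr_alpha}",
            f"feature mode        {self.feature_mode} ({self.kernel} kernel, C={self.C})",
            f"sensitivity         {r.sensitivity:.4f} ({r.correct_patients}/{r.total_patients})",
            f"specificity         {r.specificity:.4f} ({r.correct_controls}/{r.total_controls})",
            f"accuracy            {r.accuracy:.4f} "
            f"({r.correct_patients + r.correct_controls}/{r.total_patients + r.total_controls})",
        ]
        if r.auc is not None:
            lines.append(f"AUC                 {r.auc:.4f}")
        if r.perm_p is not None:
            lines.append(f"permutation p       {r.perm_p:.4g}")
        lines.append("-" * 52)
        lines.append("stable feature sets (recurrence >= tau):")
        for t in sorted(self.stable_sets, reverse=True):
            lines.append(f"  tau = {t:.2f}      {len(self.stable_sets[t])} edges")
        return "\n".join(lines)


@dataclass
class SeverityResults:
    """CSI table plus its correlations with the clinical scores."""

    table: pd.DataFrame
    correlations: list[dict]
    tau: float

    @property
    def csi(self) -> np.ndarray:
        return self.table["csi"].to_numpy()

    def summary(self) -> str:
        lines = [
            f"Connectivity severity index (tau = {self.tau})",
            "=" * 52,
            f"patients            {len(self.table)}",
            f"mean CSI            {self.csi.mean():.12f}",
            "-" * 52,
            f"{'score':<18}{'r':>8}{'p':>12}",
        ]
        for rec in self.correlations:
            lines.append(f"{rec['variable']:<18}{rec['r']:>8.3f}{rec['p']:>12.3g}")
        return "\n".join(lines)
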