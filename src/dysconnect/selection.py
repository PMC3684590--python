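"""Fold-wise feature selection with a permutation empirical null.

For each leave-one-out fold, the training subjects pass through two filters:

1. **Group-difference filter.**  Every edge gets a two-sample t-test p-value
   comparing patients and controls.  Group labels are then randomly permuted
   (1000 times by default, one joint shuffle across all edges per iteration),
   the t-test repeated, and the resulting per-edge null distribution used to
   keep an edge only when its observed p sits in the lower ``p_level`` tail
   of its own null — i.e. a permutation p-value
   ``(1 + #{null |t| >= observed |t|}) / (n_permutations + 1) <= p_level``.
2. **Quality-of-life filter.**  Among training patients, the edge must also
   correlate with the NDI quality-of-life score at ``corr_alpha``.

Edges surviving both filters form that fold's feature subset; an edge's
recurrence rate M/N over the N folds is compared with the overlap threshold
tau to build the stable feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "SelectionParams",
    "FeatureSubset",
    "StableFeatureSet",
    "group_ttest",
    "permutation_filter",
    "qol_correlation_filter",
    "select_features",
    "fold_subsets",
    "stabilize",
]


@dataclass
class SelectionParams:
    """Knobs of the two-filter selection.

    p_level is the significance level P of the permutation-null filter
    (explored over 0.05 .. 0.00001); corr_alpha the level of the
    quality-of-life correlation filter; the per-fold permutation stream is
    derived deterministically from (seed, fold index).
    """

    p_level: float = 0.01
    n_permutations: int = 1000
    corr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_level < 1.0:
            raise ValueError("p_level must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if not 0.0 < self.corr_alpha <= 1.0:
            raise ValueError("corr_alpha must be in (0, 1]")


@dataclass
class FeatureSubset:
    """Edges selected by one leave-one-out fold (fold_id = left-out row)."""

    fold_id: int
    indices: np.ndarray


@dataclass
class StableFeatureSet:
    """Edges whose recurrence rate M/N over folds reaches tau."""

    indices: np.ndarray
    recurrence: pd.Series  # rate for every edge selected in >= 1 fold
    tau: float
    n_folds: int

    def __len__(self) -> int:
        return self.indices.size


def _tstats(sum1, ssq1, n1, sum2, ssq2, n2):
    """Pooled-variance two-sample t from per-group sums and sums of squares."""
    m1 = sum1 / n1
    m2 = sum2 / n2
    ss = (ssq1 - n1 * m1**2) + (ssq2 - n2 * m2**2)
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ss / df
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, df


def group_ttest(healthy: np.ndarray, patient: np.ndarray):
    """Two-sided pooled two-sample t-test per edge.

    Returns (t, p) arrays; edges with zero pooled variance come back NaN
    (flagged rather than raised — inside folds they count as
    non-significant).
    """
    healthy = np.atleast_2d(np.asarray(healthy, dtype=float))
    patient = np.atleast_2d(np.asarray(patient, dtype=float))
    n1, n2 = healthy.shape[0], patient.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    t, df = _tstats(healthy.sum(0), (healthy**2).sum(0), n1,
                    patient.sum(0), (patient**2).sum(0), n2)
    with np.errstate(invalid="ignore"):
        p = 2.0 * special.stdtr(df, -np.abs(t))
    return t, p


def _permutation_null_abs_t(stacked: np.ndarray, n1: int, n_permutations: int,
                            rng: np.random.Generator) -> np.ndarray:
    """|t| under n_permutations joint label shuffles; shape (n_perm, E).

    One shuffle reassigns all edges at once (a single full-width t-test
    pass), preserving the cross-edge dependence of the data.
    """
    n = stacked.shape[0]
    ssq_tot = (stacked**2).sum(0)
    sum_tot = stacked.sum(0)
    # boolean membership matrix: each row a random subset of size n1
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    member = (order < n1).astype(float)
    sum1 = member @ stacked
    ssq1 = member @ (stacked**2)
    t, _ = _tstats(sum1, ssq1, n1, sum_tot - sum1, ssq_tot - ssq1, n - n1)
    return np.abs(t)


def permutation_filter(
    healthy: np.ndarray,
    patient: np.ndarray,
    p_level: float,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Boolean mask of edges whose group difference beats the empirical null.

    Retention rule: the observed p-value must rank within the p_level tail
    of the permutation distribution, i.e.
    ``(1 + #{null |t| >= |t_obs|}) / (n_permutations + 1) <= p_level``
    (equivalent to comparing observed vs null p-values, since the degrees of
    freedom are shared).  Degenerate (zero-variance) edges are dropped.
    """
    healthy = np.atleast_2d(np.asarray(healthy, dtype=float))
    patient = np.atleast_2d(np.asarray(patient, dtype=float))
    t_obs, _ = group_ttest(healthy, patient)
    abs_obs = np.abs(t_obs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stacked = np.vstack([healthy, patient])
    null_abs = _permutation_null_abs_t(stacked, healthy.shape[0], n_permutations, rng)
    # NaN (degenerate) null stats can never exceed; NaN observed never retained
    exceed = np.nansum(null_abs >= abs_obs[None, :], axis=0)
    perm_p = (1.0 + exceed) / (n_permutations + 1.0)
    mask = perm_p <= p_level
    mask &= np.isfinite(t_obs)
    return mask


def qol_correlation_filter(
    patient: np.ndarray, qol: np.ndarray, corr_alpha: float
) -> np.ndarray:
    """Edges whose patient values correlate with NDI quality-of-life.

    Two-sided Pearson test at level corr_alpha over the patient group.
    """
    patient = np.atleast_2d(np.asarray(patient, dtype=float))
    qol = np.asarray(qol, dtype=float)
    n2 = patient.shape[0]
    if n2 < 4:
        raise ValueError("need at least 4 patients for the correlation filter")
    if qol.shape[0] != n2:
        raise ValueError("qol vector length must match patient rows")
    if np.ptp(qol) == 0:
        raise ValueError("quality-of-life scores are constant")
    x = patient - patient.mean(0)
    y = qol - qol.mean()
    denom = np.sqrt((x**2).sum(0) * (y**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x * y[:, None]).sum(0) / denom
    r = np.clip(r, -1.0, 1.0)
    df = n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    t = np.where(np.abs(r) == 1.0, np.inf * np.sign(r), t)
    p = 2.0 * special.stdtr(df, -np.abs(t))
    mask = p <= corr_alpha
    mask &= np.isfinite(r)
    return mask


def select_features(
    healthy: np.ndarray,
    patient: np.ndarray,
    qol: np.ndarray,
    params: SelectionParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-training-set selection: intersection of the two filters."""
    rng = rng or np.random.default_rng(params.seed)
    keep = permutation_filter(healthy, patient, params.p_level,
                              params.n_permutations, rng)
    keep &= qol_correlation_filter(patient, qol, params.corr_alpha)
    return np.flatnonzero(keep)


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def fold_subsets(features, labels, qol, params: SelectionParams) -> list[FeatureSubset]:
    """Leave-one-out selection: one FeatureSubset per held-out subject.

    ``labels`` is boolean (True = patient) or the strings patient/control;
    ``qol`` gives every subject's NDI quality-of-life score (only patients'
    values feed the correlation filter).  Fold k never sees subject k.
    """
    x = _as_matrix(features)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        labels = labels == "patient"
    labels = labels.astype(bool)
    qol = np.asarray(qol, dtype=float)
    n = x.shape[0]
    if labels.sum() < 5:
        raise ValueError("need at least 5 patients for fold-wise selection")
    if (~labels).sum() < 3:
        raise ValueError("need at least 3 controls for fold-wise selection")
    subsets = []
    for k in range(n):
        tr = np.ones(n, dtype=bool)
        tr[k] = False
        pat = labels & tr
        con = ~labels & tr
        if pat.sum() < 2 or con.sum() < 2:
            raise ValueError(f"fold {k} loses a whole group")
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), k]))
        idx = select_features(x[con], x[pat], qol[pat], params, rng)
        subsets.append(FeatureSubset(fold_id=k, indices=idx))
    return subsets


def stabilize(subsets: list[FeatureSubset], tau: float) -> StableFeatureSet:
    """Keep edges whose recurrence rate M/N over the folds reaches tau."""
    if not subsets:
        raise ValueError("no fold subsets given")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    n = len(subsets)
    counts: dict[int, int] = {}
    for sub in subsets:
        for k in np.asarray(sub.indices, dtype=int):
            counts[int(k)] = counts.get(int(k), 0) + 1
    if counts:
        rec = pd.Series(counts, dtype=float).sort_index() / n
    else:
        rec = pd.Series(dtype=float)
    keep = rec[rec >= tau]
    return StableFeatureSet(
        indices=keep.index.to_numpy(dtype=int),
        recurrence=rec,
        tau=tau,
        n_folds=n,
    )
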