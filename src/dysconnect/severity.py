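"""Clinical-score prediction and the connectivity severity index (CSI).

Patients' NDI quality-of-life scores are predicted from the stable abnormal
connections by leave-one-out support-vector regression (linear kernel,
epsilon-insensitive loss); the out-of-fold predictions are normalized so
their mean is exactly 1.0, giving each patient a dimensionless connectivity
severity index — the lower the CSI, the more severe the illness.  The same
machinery predicts the other clinical scores (symptom, SDS, SAS, duration)
whose quality is summarized by per-patient relative errors
|predicted - actual| / actual.

Correlation reporting uses Pearson r with two-sided p-values; partial
correlations residualize both variables on the covariates (ordinary least
squares with intercept) and correlate the residuals, with the p-value
degrees of freedom reduced by the covariate count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "predict_scores",
    "relative_error",
    "compute_csi",
    "partial_correlation",
    "csi_correlations",
    "edge_qol_partial_corr",
]


def predict_scores(
    features,
    targets,
    stable_indices,
    kernel: str = "linear",
    C: float = 1.0,
    epsilon: float = 0.1,
) -> np.ndarray:
    """Leave-one-out SVR prediction of a clinical score over patients.

    ``features`` are the patients' edge vectors; only the stable feature
    columns enter the regression.  Features and target are standardized with
    training-fold statistics.  Returns one out-of-fold prediction per patient.
    """
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    idx = np.asarray(
        stable_indices.indices if hasattr(stable_indices, "indices") else stable_indices,
        dtype=int,
    )
    if idx.size == 0:
        raise ValueError("stable feature set is empty")
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 patients")
    if np.ptp(y) == 0:
        raise ValueError("target score is constant")
    xs = x[:, idx]
    pred = np.empty(n)
    for k in range(n):
        tr = np.ones(n, dtype=bool)
        tr[k] = False
        fsc = StandardScaler().fit(xs[tr])
        ym, ysd = y[tr].mean(), y[tr].std()
        ysd = ysd if ysd > 0 else 1.0
        reg = SVR(kernel=kernel, C=C, epsilon=epsilon)
        reg.fit(fsc.transform(xs[tr]), (y[tr] - ym) / ysd)
        pred[k] = reg.predict(fsc.transform(xs[k][None]))[0] * ysd + ym
    return pred


def relative_error(predicted, actual) -> np.ndarray:
    """Per-subject |predicted - actual| / actual; actual = 0 -> NaN (excluded
    from any mean)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(predicted - actual) / actual
    return np.where(actual == 0, np.nan, err)


def compute_csi(predicted_qol, patients: pd.DataFrame | None = None) -> pd.DataFrame:
    """Connectivity severity index: predictions scaled so their mean is 1.0.

    ``patients`` optionally supplies the actual clinical scores to carry in
    the table (subject_id, ndi_symptom, sds, sas, duration_months, ...).
    """
    pred = np.asarray(predicted_qol, dtype=float)
    if pred.size < 2:
        raise ValueError("need at least 2 patients")
    mean = pred.mean()
    if mean == 0:
        raise ValueError("mean predicted score is zero; CSI undefined")
    csi = pred / mean
    table = pd.DataFrame({"predicted_qol": pred, "csi": csi})
    if patients is not None:
        patients = patients.reset_index(drop=True)
        for col in ("subject_id", "ndi_qol", "ndi_symptom", "sds", "sas",
                    "duration_months", "age_years"):
            if col in patients.columns:
                table[col] = patients[col].to_numpy()
    return table


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), covariates])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out the covariates.

    Returns (r, p); degrees of freedom are n - 2 - k for k covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != x.shape[0]:
        cov = cov.T
    k = cov.shape[1]
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("residual variance is zero")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = len(x) - 2 - k
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    rr = min(abs(r), 1.0 - 1e-15)
    t = rr * np.sqrt(df / (1.0 - rr**2))
    p = 2.0 * float(special.stdtr(df, -t))
    return r, p


def csi_correlations(
    csi_table: pd.DataFrame,
    score_cols: tuple[str, ...] = ("ndi_symptom", "sds", "sas", "duration_months"),
    control_for: tuple[str, ...] = (),
) -> list[dict]:
    """Pearson and (optionally) partial correlations of the CSI with each
    clinical score.

    ``control_for`` names covariate columns regressed out of both the CSI
    and the score before the partial coefficient.
    """
    if len(csi_table) < 5:
        raise ValueError("need at least 5 patients")
    csi = csi_table["csi"].to_numpy(dtype=float)
    out = []
    for col in score_cols:
        if col not in csi_table.columns:
            continue
        y = csi_table[col].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(csi) == 0:
            raise ValueError(f"constant column in correlation: {col}")
        r, p = stats.pearsonr(csi, y)
        rec = {"variable": col, "r": float(r), "p": float(p),
               "covariates": list(control_for)}
        covs = [c for c in control_for if c != col]
        if covs:
            cov = csi_table[list(covs)].to_numpy(dtype=float)
            pr, pp = partial_correlation(csi, y, cov)
            rec["partial_r"], rec["partial_p"] = pr, pp
            rec["covariates"] = covs
        out.append(rec)
    return out


def edge_qol_partial_corr(features, qol, age, indices=None) -> np.ndarray:
    """Per-edge partial Pearson r with quality-of-life, controlling age.

    Computed across all supplied subjects; the sign of the coefficient drives
    the network report's negative/positive split.
    """
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    if indices is not None:
        idx = np.asarray(
            indices.indices if hasattr(indices, "indices") else indices, dtype=int
        )
        x = x[:, idx]
    qol = np.asarray(qol, dtype=float)
    age = np.asarray(age, dtype=float)
    n = x.shape[0]
    if np.ptp(qol) == 0:
        raise ValueError("quality-of-life scores are constant")
    design = np.column_stack([np.ones(n), age])
    beta_q, *_ = np.linalg.lstsq(design, qol, rcond=None)
    rq = qol - design @ beta_q
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    rx = x - design @ beta_x
    rxc = rx - rx.mean(0)
    rqc = rq - rq.mean()
    denom = np.sqrt((rxc**2).sum(0) * (rqc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rxc * rqc[:, None]).sum(0) / denom
    return r
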