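"""Time-series conditioning and vectorized functional-connectivity features.

A subject's conditioned ROI time series (T timepoints x R regions) is turned
into a feature vector of length R(R-1)/2 by taking the Pearson correlation of
every ROI pair, applying Fisher's r-to-z transform, and linearizing the strict
upper triangle of the symmetric correlation matrix row-major.  With the
1024-node whole-brain parcellation this yields 523776 features per subject.

Conditioning follows the usual resting-state order: linear detrend and
0.01-0.08 Hz band-pass first, then regression of nuisance signals (white
matter, CSF, ventricles, motion summaries) supplied by the caller as a
T x K matrix.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FeatureIndexMap",
    "session_volumes",
    "discard_initial",
    "detrend_bandpass",
    "regress_nuisance",
    "connectivity_vector",
    "cohort_feature_matrix",
    "write_features",
    "read_features",
]

# |r| at or above this bound is clipped before atanh so z stays finite
_R_CLIP = 1.0 - 1e-12


class FeatureIndexMap:
    """Bijection between linear feature index k and ROI pair (i, j), i < j.

    Ordering is row-major over the strict upper triangle, so for R ROIs
    k runs 0 .. R(R-1)/2 - 1 with (0,1) first and (R-2, R-1) last.
    """

    def __init__(self, n_rois: int):
        if n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        self.n_rois = int(n_rois)
        self._i, self._j = np.triu_indices(self.n_rois, k=1)

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    @property
    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self._i, self._j

    def index_of(self, i, j):
        """Linear index of pair (i, j); order of i and j does not matter."""
        i = np.asarray(i)
        j = np.asarray(j)
        if np.any(i == j):
            raise ValueError("diagonal pairs have no feature index")
        lo = np.minimum(i, j).astype(np.int64)
        hi = np.maximum(i, j).astype(np.int64)
        if np.any(lo < 0) or np.any(hi >= self.n_rois):
            raise ValueError("ROI out of range")
        r = self.n_rois
        k = lo * r - lo * (lo + 1) // 2 + (hi - lo - 1)
        return k if k.ndim else int(k)

    def pair_of(self, k):
        k = np.asarray(k)
        if np.any(k < 0) or np.any(k >= self.n_edges):
            raise ValueError("feature index out of range")
        i = self._i[k]
        j = self._j[k]
        if i.ndim:
            return i, j
        return int(i), int(j)

    def to_json(self) -> str:
        return json.dumps(
            {"n_rois": self.n_rois, "n_edges": self.n_edges, "order": "row-major-upper"}
        )


def session_volumes(session_minutes: float = 6.0, tr_seconds: float = 2.0) -> int:
    """Number of whole-brain volumes acquired in a session (6 min at TR=2 s -> 180)."""
    if session_minutes <= 0 or tr_seconds <= 0:
        raise ValueError("session length and TR must be positive")
    return int(round(session_minutes * 60.0 / tr_seconds))


def discard_initial(values: np.ndarray, n_discard: int = 10) -> np.ndarray:
    """Drop the first `n_discard` volumes (magnetization non-equilibrium)."""
    values = np.asarray(values)
    if n_discard < 0 or n_discard >= values.shape[0]:
        raise ValueError("n_discard must be in [0, T)")
    return values[n_discard:]


def detrend_bandpass(
    values: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    method: str = "fft",
    order: int = 4,
) -> np.ndarray:
    """Linearly detrend each column, then band-pass it to [low_hz, high_hz].

    The default realization is an ideal frequency-domain mask (rectangular
    band on the real FFT bins); a zero-phase Butterworth filter is available
    with ``method="butterworth"``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a T x R matrix")
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist={nyquist}"
        )
    x = signal.detrend(values, axis=0, type="linear")
    if method == "fft":
        t = x.shape[0]
        spec = np.fft.rfft(x, axis=0)
        freqs = np.fft.rfftfreq(t, d=tr_seconds)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spec[~keep] = 0.0
        return np.fft.irfft(spec, n=t, axis=0)
    if method == "butterworth":
        sos = signal.butter(
            order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos"
        )
        return signal.sosfiltfilt(sos, x, axis=0)
    raise ValueError(f"unknown filter method {method!r}")


def regress_nuisance(values: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Regress a T x K nuisance matrix (plus intercept) out of every column.

    Residuals are orthogonal to each regressor.  A rank-deficient design
    triggers a warning and a pseudo-inverse (minimum-norm) fit.
    """
    values = np.asarray(values, dtype=float)
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    t = values.shape[0]
    if regressors.shape[0] != t:
        raise ValueError("regressors must have the same number of rows as the data")
    if regressors.shape[1] >= t:
        raise ValueError("more regressors than timepoints")
    design = np.column_stack([np.ones(t), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "nuisance design is rank deficient; using pseudo-inverse fit",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = np.linalg.pinv(design) @ values
    return values - design @ beta


def connectivity_vector(values: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity features of one subject's T x R time series.

    Entry k is atanh(Pearson r) of ROI pair ``FeatureIndexMap(R).pair_of(k)``.
    Correlations with |r| >= 1 - 1e-12 (e.g. duplicated ROI signals) are
    clipped to keep the transform finite; a warning reports how many.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a T x R matrix")
    t, r = values.shape
    if t < 4:
        raise ValueError("need at least 4 timepoints")
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"ROI {dead[0]} has zero variance (constant signal)")
    corr = np.corrcoef(values, rowvar=False)
    iu, ju = np.triu_indices(r, k=1)
    rvals = corr[iu, ju]
    extreme = np.abs(rvals) >= _R_CLIP
    if extreme.any():
        warnings.warn(
            f"{int(extreme.sum())} ROI pair(s) with |r|~1 clipped before r-to-z",
            RuntimeWarning,
            stacklevel=2,
        )
        rvals = np.clip(rvals, -_R_CLIP, _R_CLIP)
    return np.arctanh(rvals)


def cohort_feature_matrix(
    timeseries: dict[str, np.ndarray],
    tr_seconds: float = 2.0,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    nuisance: dict[str, np.ndarray] | None = None,
    condition: bool = True,
) -> pd.DataFrame:
    """Condition every subject's time series and stack feature vectors.

    Returns a DataFrame indexed by subject id with one column per linear
    edge index.  ``nuisance`` optionally maps subject id -> T x K matrix.
    """
    rows = {}
    for sid, ts in timeseries.items():
        x = np.asarray(ts, dtype=float)
        if condition:
            x = detrend_bandpass(x, tr_seconds, low_hz, high_hz)
            if nuisance is not None and sid in nuisance:
                x = regress_nuisance(x, nuisance[sid])
        rows[sid] = connectivity_vector(x)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def write_features(df: pd.DataFrame, path, n_rois: int | None = None) -> None:
    """One-row-per-subject CSV plus a sidecar JSON index map."""
    df.to_csv(path, float_format="%.10g")
    if n_rois is None:
        # invert E = R(R-1)/2
        e = df.shape[1]
        n_rois = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    with open(str(path) + ".map.json", "w") as fh:
        fh.write(FeatureIndexMap(n_rois).to_json())


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(int)
    return df
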