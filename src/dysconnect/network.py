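"""Characterization of the stable abnormal network.

Each stable edge is annotated with its ROI pair, Euclidean length between
the ROI centroids (mm), and the sign of its partial correlation with the
NDI quality-of-life score (controlling age).  Node weights count how often
each ROI participates in abnormal connections; the sign split compares the
lengths of negatively vs positively correlated connections with a two-sample
t-test; per-system tallies report the fraction of negative connections
touching each cortical system.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import FeatureIndexMap
from .severity import edge_qol_partial_corr

__all__ = [
    "node_weights",
    "connection_lengths",
    "annotate_edges",
    "sign_split_length_test",
    "system_proportions",
    "write_edge_list",
]


def _indices(stable) -> np.ndarray:
    return np.asarray(
        stable.indices if hasattr(stable, "indices") else stable, dtype=int
    )


def node_weights(stable, n_rois: int) -> pd.Series:
    """Occurrence count of each ROI across the stable edges.

    The handshake identity holds: weights sum to twice the edge count.
    """
    idx = _indices(stable)
    if idx.size == 0:
        raise ValueError("stable feature set is empty")
    fmap = FeatureIndexMap(n_rois)
    i, j = fmap.pair_of(idx)
    counts = np.bincount(np.concatenate([np.atleast_1d(i), np.atleast_1d(j)]),
                         minlength=n_rois)
    s = pd.Series(counts, index=pd.RangeIndex(n_rois, name="roi_id"), name="weight")
    return s


def _centroids(atlas: pd.DataFrame) -> pd.DataFrame:
    return atlas.set_index("roi_id")[["x_mm", "y_mm", "z_mm"]]


def connection_lengths(stable, atlas: pd.DataFrame) -> np.ndarray:
    """3-D Euclidean distance (mm) between the centroids of each edge's ROIs."""
    idx = _indices(stable)
    n_rois = int(atlas["roi_id"].max()) + 1
    fmap = FeatureIndexMap(n_rois)
    i, j = fmap.pair_of(idx)
    cent = _centroids(atlas)
    for roi in np.unique(np.concatenate([np.atleast_1d(i), np.atleast_1d(j)])):
        if roi not in cent.index or cent.loc[roi].isna().any():
            raise ValueError(f"missing centroid for ROI {roi}")
    a = cent.loc[np.atleast_1d(i)].to_numpy(dtype=float)
    b = cent.loc[np.atleast_1d(j)].to_numpy(dtype=float)
    return np.linalg.norm(a - b, axis=1)


def annotate_edges(stable, atlas: pd.DataFrame, features, qol, age) -> pd.DataFrame:
    """Edge table: ROI pair, length, QoL partial correlation and its sign.

    ``features`` spans all subjects (patients and controls) over the full
    edge set; correlation is computed across all subjects controlling age.
    A coefficient of exactly 0 counts as positive (tie-break; unreachable on
    continuous data).
    """
    idx = _indices(stable)
    if idx.size == 0:
        raise ValueError("stable feature set is empty")
    n_rois = int(atlas["roi_id"].max()) + 1
    fmap = FeatureIndexMap(n_rois)
    i, j = fmap.pair_of(idx)
    i, j = np.atleast_1d(i), np.atleast_1d(j)
    r = edge_qol_partial_corr(features, qol, age, indices=idx)
    systems = atlas.set_index("roi_id")["system"]
    df = pd.DataFrame({
        "edge_index": idx,
        "roi_i": i,
        "roi_j": j,
        "length_mm": connection_lengths(idx, atlas),
        "qol_r": r,
        "qol_sign": np.where(r < 0, "negative", "positive"),
        "system_i": systems.loc[i].to_numpy(),
        "system_j": systems.loc[j].to_numpy(),
    })
    return df


def sign_split_length_test(annotations: pd.DataFrame) -> dict:
    """Mean/SD length per QoL-correlation sign plus a two-sample t-test."""
    neg = annotations.loc[annotations["qol_sign"] == "negative", "length_mm"].to_numpy()
    pos = annotations.loc[annotations["qol_sign"] == "positive", "length_mm"].to_numpy()
    out = {
        "n_negative": int(neg.size),
        "n_positive": int(pos.size),
        "mean_negative_mm": float(neg.mean()) if neg.size else np.nan,
        "sd_negative_mm": float(neg.std(ddof=1)) if neg.size > 1 else np.nan,
        "mean_positive_mm": float(pos.mean()) if pos.size else np.nan,
        "sd_positive_mm": float(pos.std(ddof=1)) if pos.size > 1 else np.nan,
        "frac_negative": float(neg.size / max(neg.size + pos.size, 1)),
    }
    if neg.size < 2 or pos.size < 2:
        warnings.warn("a sign group has fewer than 2 edges; length test skipped",
                      RuntimeWarning, stacklevel=2)
        out["t"] = np.nan
        out["p"] = np.nan
        return out
    t, p = stats.ttest_ind(neg, pos)
    out["t"] = float(t)
    out["p"] = float(p)
    return out


def system_proportions(annotations: pd.DataFrame, assignment: str = "both") -> pd.DataFrame:
    """Negative/positive connection counts and fractions per cortical system.

    ``assignment="both"`` counts an edge once toward every system it touches
    (once if both ends share the system); ``"first"`` assigns each edge only
    to its first ROI's system.
    """
    if annotations[["system_i", "system_j"]].isna().any().any():
        raise ValueError("unlabeled ROI in annotations")
    rows = {}
    for _, e in annotations.iterrows():
        if assignment == "both":
            touched = {e["system_i"], e["system_j"]}
        elif assignment == "first":
            touched = {e["system_i"]}
        else:
            raise ValueError(f"unknown assignment {assignment!r}")
        for sysname in touched:
            rec = rows.setdefault(sysname, {"n_negative": 0, "n_positive": 0})
            rec["n_negative" if e["qol_sign"] == "negative" else "n_positive"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "system"
    total = df["n_negative"] + df["n_positive"]
    df["frac_negative"] = df["n_negative"] / total
    df["frac_positive"] = df["n_positive"] / total
    return df


def write_edge_list(annotations: pd.DataFrame, path, weight_col: str = "qol_r") -> None:
    """Plain edge-list text (roi_i roi_j weight) for external graph viewers."""
    with open(path, "w") as fh:
        for _, e in annotations.iterrows():
            fh.write(f"{int(e['roi_i'])}\t{int(e['roi_j'])}\t{e[weight_col]:.6g}\n")
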