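"""End-to-end orchestration: simulate -> features -> select -> classify ->
severity -> network report, with deterministic seeding and provenance.

A single `RunConfig` drives the run; every artifact is CSV or JSON in the
output directory, floats rounded to 10 significant digits so identical
configs reproduce byte-identical files.  Fold subsets are computed once per
significance level and reused across the tau sweep and the per-fold LOOCV.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import connectome as _connectome
from . import network as _network
from . import severity as _severity
from . import synthetic as _synthetic
from .selection import SelectionParams, fold_subsets, stabilize

__all__ = ["RunConfig", "run_pipeline", "sweep_p_levels"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Parameters of one end-to-end run (desk-scale defaults)."""

    seed: int = 0
    n_rois: int = 90
    p_level: float = 0.01
    corr_alpha: float = 0.05
    n_permutations: int = 200
    tau_list: tuple[float, ...] = (1.0, 0.95, 0.90, 0.85)
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    tr_seconds: float = 2.0
    n_patients: int = 20
    n_controls: int = 20
    n_rep_patients: int = 9
    n_rep_controls: int = 8
    feature_mode: str = "per_fold"
    use_timeseries: bool = False
    t_points: int = 180
    n_planted: int = 10
    kernel: str = "linear"
    svm_c: float = 1.0

    def __post_init__(self):
        self.tau_list = tuple(float(t) for t in self.tau_list)
        if any(not 0 < t <= 1 for t in self.tau_list):
            raise ValueError("tau values must lie in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return asdict(self)


def _make_data(config: RunConfig):
    effects = _synthetic.PlantedEffectMap.default(
        config.n_rois, n_planted=config.n_planted, seed=config.seed
    )
    cohort = _synthetic.generate_cohort(config.n_patients, config.n_controls,
                                        seed=config.seed)
    rep = _synthetic.generate_cohort(config.n_rep_patients, config.n_rep_controls,
                                     seed=config.seed + 1)
    rep["subject_id"] = "R" + rep["subject_id"]
    atlas = _synthetic.generate_atlas(config.n_rois, seed=config.seed)
    if config.use_timeseries:
        ts = _synthetic.generate_timeseries_cohort(
            cohort, config.n_rois, effects, t_points=config.t_points,
            tr_seconds=config.tr_seconds, seed=config.seed)
        ts_rep = _synthetic.generate_timeseries_cohort(
            rep, config.n_rois, effects, t_points=config.t_points,
            tr_seconds=config.tr_seconds, seed=config.seed + 1)
        feats = _connectome.cohort_feature_matrix(
            ts, config.tr_seconds, config.band_low_hz, config.band_high_hz)
        feats_rep = _connectome.cohort_feature_matrix(
            ts_rep, config.tr_seconds, config.band_low_hz, config.band_high_hz)
    else:
        feats = _synthetic.generate_edge_data(cohort, config.n_rois, effects,
                                              seed=config.seed)
        feats_rep = _synthetic.generate_edge_data(rep, config.n_rois, effects,
                                                  seed=config.seed + 1)
    return cohort, rep, atlas, feats, feats_rep, effects


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write all artifacts under ``outdir``.

    Returns a dict of the in-memory results keyed like the files.
    """
    os.makedirs(outdir, exist_ok=True)
    path = lambda name: os.path.join(outdir, name)
    cohort, rep, atlas, feats, feats_rep, effects = _make_data(config)
    _synthetic.write_cohort(cohort, path("cohort.csv"), config.seed, config.to_dict())
    _synthetic.write_cohort(rep, path("replication_cohort.csv"), config.seed + 1, {})
    _synthetic.write_atlas(atlas, path("atlas.csv"), config.seed, {})
    _connectome.write_features(feats, path("features.csv"), config.n_rois)
    _connectome.write_features(feats_rep, path("replication_features.csv"), config.n_rois)

    labels = (cohort["group"] == "patient").to_numpy()
    qol = cohort["ndi_qol"].to_numpy(dtype=float)
    params = SelectionParams(config.p_level, config.n_permutations,
                             config.corr_alpha, config.seed)
    subsets = fold_subsets(feats, labels, qol, params)
    pd.DataFrame(
        [(s.fold_id, k) for s in subsets for k in s.indices],
        columns=["fold_id", "edge_index"],
    ).to_csv(path("fold_subsets.csv"), index=False)

    fmap = _connectome.FeatureIndexMap(config.n_rois)
    stable = {}
    for tau in config.tau_list:
        st = stabilize(subsets, tau)
        stable[tau] = st
        if len(st):
            i, j = fmap.pair_of(st.indices)
            tab = pd.DataFrame({
                "edge_index": st.indices,
                "roi_i": np.atleast_1d(i),
                "roi_j": np.atleast_1d(j),
                "recurrence_rate": st.recurrence.loc[st.indices].to_numpy(),
            })
        else:
            tab = pd.DataFrame(columns=["edge_index", "roi_i", "roi_j", "recurrence_rate"])
        tab.to_csv(path(f"stable_tau{int(round(tau * 100))}.csv"), index=False,
                   float_format=_FLOAT_FMT)

    results = {"stable": stable, "cohort": cohort, "atlas": atlas, "features": feats}
    report, decisions = _classify.loocv_classify(
        feats, labels, qol, params, feature_mode=config.feature_mode,
        tau=config.tau_list[0], kernel=config.kernel, C=config.svm_c,
        subsets=subsets if config.feature_mode == "per_fold" else None,
        return_decisions=True)
    results["classification"] = report
    with open(path("classification.json"), "w") as fh:
        json.dump({"feature_mode": config.feature_mode, "p_level": config.p_level,
                   **report.to_dict()}, fh, indent=2)
    fpr, tpr, thr, auc = _classify.roc_points(decisions, labels)
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
        path("roc.csv"), index=False, float_format=_FLOAT_FMT)

    rep_labels = (rep["group"] == "patient").to_numpy()
    rep_reports = {}
    for tau, st in stable.items():
        if len(st) == 0:
            continue
        rr = _classify.replicate_classify(feats, labels, st, feats_rep, rep_labels,
                                          kernel=config.kernel, C=config.svm_c)
        rep_reports[tau] = rr
    with open(path("replication.json"), "w") as fh:
        json.dump({f"tau_{t}": r.to_dict() for t, r in rep_reports.items()}, fh, indent=2)
    results["replication"] = rep_reports

    # severity stage at the first tau with a nonempty stable set
    sev_tau = next((t for t in config.tau_list if len(stable[t])), None)
    if sev_tau is not None:
        pats = cohort[labels].reset_index(drop=True)
        pred = _severity.predict_scores(
            feats.to_numpy(dtype=float)[labels], pats["ndi_qol"].to_numpy(dtype=float),
            stable[sev_tau], kernel=config.kernel, C=config.svm_c)
        csi = _severity.compute_csi(pred, pats)
        csi.to_csv(path("csi.csv"), index=False, float_format=_FLOAT_FMT)
        corr = _severity.csi_correlations(csi) if len(csi) >= 5 else []
        with open(path("csi_correlations.json"), "w") as fh:
            json.dump({"tau": sev_tau, "correlations": corr}, fh, indent=2)
        results["csi"] = csi

        ann = _network.annotate_edges(
            stable[sev_tau], atlas, feats, qol,
            cohort["age_years"].to_numpy(dtype=float))
        ann.to_csv(path("network_edges.csv"), index=False, float_format=_FLOAT_FMT)
        _network.write_edge_list(ann, path("network_edges.txt"))
        _network.node_weights(stable[sev_tau], config.n_rois).to_csv(
            path("network_nodes.csv"))
        stats = {
            "length_test": _network.sign_split_length_test(ann),
            "system_proportions": _network.system_proportions(ann).to_dict("index"),
        }
        with open(path("network_stats.json"), "w") as fh:
            json.dump(stats, fh, indent=2, default=float)
        results["network"] = {"annotations": ann, **stats}

    with open(path("manifest.json"), "w") as fh:
        json.dump({"config": config.to_dict(), "seed": config.seed,
                   "planted_edges": effects.feature_indices.tolist()}, fh, indent=2)
    return results


def sweep_p_levels(config: RunConfig, levels) -> pd.DataFrame:
    """LOOCV accuracy per significance level; the argmax row is the paper-style
    operating point."""
    levels = list(levels)
    if any(not 0 < lv < 1 for lv in levels):
        raise ValueError("levels must lie in (0, 1)")
    cohort, _, _, feats, _, _ = _make_data(config)
    labels = (cohort["group"] == "patient").to_numpy()
    qol = cohort["ndi_qol"].to_numpy(dtype=float)
    rows = []
    for lv in levels:
        params = SelectionParams(lv, config.n_permutations, config.corr_alpha,
                                 config.seed)
        subsets = fold_subsets(feats, labels, qol, params)
        rep = _classify.loocv_classify(feats, labels, qol, params,
                                       feature_mode="per_fold", subsets=subsets,
                                       kernel=config.kernel, C=config.svm_c)
        rows.append({"p_level": lv, "accuracy": rep.accuracy,
                     "sensitivity": rep.sensitivity, "specificity": rep.specificity,
                     "mean_n_features": float(np.mean([len(s.indices) for s in subsets]))})
    df = pd.DataFrame(rows)
    df.attrs["best_p_level"] = float(df.loc[df["accuracy"].idxmax(), "p_level"])
    return df
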