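"""Seeded synthetic cohorts for exercising the discrimination pipeline.

Real resting-state scans for the dyspepsia case-control design are not
publicly deposited, so every downstream stage is driven by generated data:

* a subject table with group labels and clinical scores (NDI quality-of-life,
  NDI symptom score, SDS, SAS, disease duration, age) whose means/SDs follow
  the published cohort description and whose correlation structure is induced
  by two correlated latent factors — a "gastro" factor loading on the NDI
  scores and a "mood" factor loading on SDS/SAS — with duration independent
  of everything;
* per-subject edge-level connectivity features with a sparse set of planted
  "abnormal" edges whose mean differs between groups and which co-vary with
  patients' quality-of-life scores (a configurable fraction negatively, the
  published network being ~65% negative);
* optionally, band-limited ROI time series realizing the planted edge
  correlations, plus linear drift and out-of-band components so the
  conditioning stage has something to remove.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .connectome import FeatureIndexMap

__all__ = [
    "ScoreModel",
    "PlantedEffectMap",
    "generate_cohort",
    "generate_atlas",
    "generate_edge_data",
    "generate_timeseries_cohort",
    "slope_for_correlation",
    "write_cohort",
    "write_atlas",
    "write_timeseries",
]

SYSTEMS = ("limbic_paralimbic", "prefrontal", "tempo_parietal", "visual", "other")

# (mean, sd) per clinical score, original-sample values
_PATIENT_SCORES = {
    "ndi_qol": (76.6503, 10.1738),
    "ndi_symptom": (47.2, 15.8668),
    "sds": (44.375, 9.9799),
    "sas": (42.625, 7.1712),
    "duration_months": (37.825, 28.2197),
    "age_years": (22.45, 1.8529),
}
_CONTROL_SCORES = {
    "ndi_qol": (87.4057, 5.4378),
    "ndi_symptom": (1.225, 1.9012),
    "sds": (33.925, 5.7708),
    "sas": (32.3, 5.8713),
    "age_years": (22.925, 1.5256),
}


@dataclass
class ScoreModel:
    """Distributional parameters of the clinical scores.

    Scores are truncated Gaussians: ``score = mean + sd * z`` with z built
    from two correlated standard-normal factors (gastro G, mood M):

        qol     loads -gastro_loading on G
        symptom loads +gastro_loading on G
        sds/sas load  +mood_loading on M and +cross_loading on G
        duration, age are independent

    then clipped to the score's admissible range (QoL to [0, 100], the rest
    to be non-negative).
    """

    patient: dict = field(default_factory=lambda: dict(_PATIENT_SCORES))
    control: dict = field(default_factory=lambda: dict(_CONTROL_SCORES))
    gastro_loading: float = 0.85
    mood_loading: float = 0.85
    cross_loading: float = 0.15
    factor_corr: float = 0.3

    def zero_variance(self) -> "ScoreModel":
        """Copy with every SD set to 0 (degenerate, for tests)."""
        pat = {k: (m, 0.0) for k, (m, _) in self.patient.items()}
        con = {k: (m, 0.0) for k, (m, _) in self.control.items()}
        return ScoreModel(pat, con, self.gastro_loading, self.mood_loading,
                          self.cross_loading, self.factor_corr)


def _draw_group(rng: np.random.Generator, n: int, params: dict, model: ScoreModel,
                with_duration: bool) -> dict[str, np.ndarray]:
    g = rng.standard_normal(n)
    m = model.factor_corr * g + np.sqrt(1 - model.factor_corr**2) * rng.standard_normal(n)
    lg, lm, c = model.gastro_loading, model.mood_loading, model.cross_loading
    resid = lambda load: np.sqrt(max(1.0 - load, 0.0))  # load = sum of squared loadings
    z = {
        "ndi_qol": -lg * g + resid(lg**2) * rng.standard_normal(n),
        "ndi_symptom": lg * g + resid(lg**2) * rng.standard_normal(n),
        "sds": lm * m + c * g + resid(lm**2 + c**2) * rng.standard_normal(n),
        "sas": lm * m + c * g + resid(lm**2 + c**2) * rng.standard_normal(n),
        "duration_months": rng.standard_normal(n),
        "age_years": rng.standard_normal(n),
    }
    out = {}
    for name, (mean, sd) in params.items():
        if name == "duration_months" and not with_duration:
            continue
        vals = mean + sd * z[name]
        if name == "ndi_qol":
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.maximum(vals, 0.0)
        out[name] = vals
    return out


def generate_cohort(
    n_patients: int,
    n_controls: int,
    score_model: ScoreModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject table for a matched case-control cohort.

    Patients carry lower quality-of-life and higher symptom/depression/anxiety
    scores in expectation; duration is independent of every score.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    model = score_model or ScoreModel()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    pat = _draw_group(rng, n_patients, model.patient, model, with_duration=True)
    con = _draw_group(rng, n_controls, model.control, model, with_duration=False)
    rows = []
    for i in range(n_patients):
        rows.append({"subject_id": f"P{i + 1:03d}", "group": "patient",
                     **{k: v[i] for k, v in pat.items()}})
    for i in range(n_controls):
        rows.append({"subject_id": f"C{i + 1:03d}", "group": "control",
                     **{k: v[i] for k, v in con.items()}})
    df = pd.DataFrame(rows)
    cols = ["subject_id", "group", "ndi_qol", "ndi_symptom", "sds", "sas",
            "duration_months", "age_years"]
    df["duration_months"] = df.get("duration_months", np.nan)
    return df[cols]


def generate_atlas(n_rois: int = 90, seed: int = 0) -> pd.DataFrame:
    """ROI atlas: centroid coordinates (mm) and a cortical-system label.

    Centroids are drawn uniformly in a brain-sized box (|x|<=70, |y|<=85,
    |z|<=60 mm); systems are assigned in fixed proportions over the five
    labels used by the network report.
    """
    if n_rois < 3:
        raise ValueError("need at least 3 ROIs")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA7]))
    xyz = rng.uniform([-70, -85, -60], [70, 85, 60], size=(n_rois, 3))
    # rough whole-brain proportions; 'other' takes the remainder
    props = {"limbic_paralimbic": 0.2, "prefrontal": 0.2, "tempo_parietal": 0.25,
             "visual": 0.15}
    labels = []
    for name, p in props.items():
        labels += [name] * int(round(p * n_rois))
    labels += ["other"] * (n_rois - len(labels))
    labels = np.array(labels[:n_rois])
    rng.shuffle(labels)
    return pd.DataFrame({
        "roi_id": np.arange(n_rois),
        "x_mm": xyz[:, 0], "y_mm": xyz[:, 1], "z_mm": xyz[:, 2],
        "system": labels,
    })


def slope_for_correlation(r: float, noise_sd: float, qol_sd: float) -> float:
    """Edge-on-QoL slope giving within-patient correlation r at the stated SDs."""
    if not -1 < r < 1:
        raise ValueError("target correlation must be in (-1, 1)")
    return r / np.sqrt(1 - r**2) * noise_sd / qol_sd


@dataclass
class PlantedEffectMap:
    """Sparse set of edges carrying a group effect and a QoL association.

    group_shift is the patient-minus-control difference of mean Fisher z;
    qol_slope ties a patient's (centered) quality-of-life score to the edge
    value, so its sign is the sign of the within-patient edge-QoL correlation.
    """

    feature_indices: np.ndarray
    group_shift: np.ndarray
    qol_slope: np.ndarray
    noise_sd: float = 1.0

    def __post_init__(self):
        self.feature_indices = np.atleast_1d(np.asarray(self.feature_indices, dtype=int))
        k = self.feature_indices.size
        self.group_shift = np.broadcast_to(
            np.asarray(self.group_shift, dtype=float), (k,)).copy()
        self.qol_slope = np.broadcast_to(
            np.asarray(self.qol_slope, dtype=float), (k,)).copy()
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if k != np.unique(self.feature_indices).size:
            raise ValueError("planted feature indices must be distinct")

    def validate(self, n_rois: int) -> None:
        n_edges = n_rois * (n_rois - 1) // 2
        if self.feature_indices.size and (
            self.feature_indices.min() < 0 or self.feature_indices.max() >= n_edges
        ):
            raise ValueError(f"planted index out of range for {n_edges} edges")

    @classmethod
    def none(cls) -> "PlantedEffectMap":
        return cls(np.empty(0, dtype=int), np.empty(0), np.empty(0), 1.0)

    @classmethod
    def default(
        cls,
        n_rois: int,
        n_planted: int = 10,
        shift_sd_units: float = 2.0,
        qol_corr: float = 0.7,
        frac_negative: float = 0.65,
        noise_sd: float = 1.0,
        qol_sd: float = _PATIENT_SCORES["ndi_qol"][1],
        seed: int = 0,
    ) -> "PlantedEffectMap":
        """Default planted network: disjoint ROI pairs, shift 2*noise_sd,
        |edge-QoL correlation| = qol_corr with 65% of slopes negative."""
        if 2 * n_planted > n_rois:
            raise ValueError("not enough ROIs for disjoint planted edges")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xED]))
        rois = rng.choice(n_rois, size=2 * n_planted, replace=False)
        fmap = FeatureIndexMap(n_rois)
        idx = np.sort(fmap.index_of(rois[0::2], rois[1::2]))
        slope = slope_for_correlation(qol_corr, noise_sd, qol_sd)
        n_neg = int(round(frac_negative * n_planted))
        signs = np.array([-1.0] * n_neg + [1.0] * (n_planted - n_neg))
        return cls(idx, shift_sd_units * noise_sd, signs * slope, noise_sd)


def generate_edge_data(
    cohort: pd.DataFrame,
    n_rois: int,
    effects: PlantedEffectMap,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject Fisher-z edge features with planted effects.

    Non-planted edges are zero-mean Gaussian noise; planted edges add the
    group shift for patients plus qol_slope times the patient's centered
    quality-of-life score.
    """
    effects.validate(n_rois)
    n_edges = n_rois * (n_rois - 1) // 2
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE0]))
    n = len(cohort)
    z = effects.noise_sd * rng.standard_normal((n, n_edges))
    is_patient = (cohort["group"] == "patient").to_numpy()
    if effects.feature_indices.size:
        z[np.ix_(is_patient, effects.feature_indices)] += effects.group_shift
        qol = cohort.loc[is_patient, "ndi_qol"].to_numpy(dtype=float)
        qc = qol - qol.mean()
        z[np.ix_(is_patient, effects.feature_indices)] += np.outer(qc, effects.qol_slope)
    df = pd.DataFrame(z, index=cohort["subject_id"].to_numpy(), columns=np.arange(n_edges))
    df.index.name = "subject_id"
    return df


def _band_signal(rng, t_points, tr_seconds, low_hz, high_hz, shape):
    """Unit-variance band-limited Gaussian signals via FFT masking."""
    t = t_points
    white = rng.standard_normal((t,) + shape)
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    spec[(freqs < low_hz) | (freqs > high_hz)] = 0.0
    x = np.fft.irfft(spec, n=t, axis=0)
    sd = np.atleast_1d(x.std(axis=0))
    sd[sd == 0] = 1.0
    return x / (sd if shape else sd[0])


def generate_timeseries_cohort(
    cohort: pd.DataFrame,
    n_rois: int,
    effects: PlantedEffectMap,
    t_points: int = 180,
    tr_seconds: float = 2.0,
    seed: int = 0,
    drift_amplitude: float = 1.0,
    outofband_amplitude: float = 0.5,
    band: tuple[float, float] = (0.01, 0.08),
) -> dict[str, np.ndarray]:
    """Band-limited ROI time series realizing the planted edge correlations.

    Each ROI gets an independent in-band signal; the two ROIs of a planted
    edge share a common in-band source with weight chosen so that their
    correlation approximates tanh(planted z).  A linear drift and an
    out-of-band (0.15 Hz) component are added so conditioning is exercised.
    Defaults mirror a 6-min session at TR = 2 s (180 volumes).
    """
    if t_points <= 20:
        raise ValueError("t_points must exceed 20")
    effects.validate(n_rois)
    fmap = FeatureIndexMap(n_rois)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x75]))
    low, high = band
    is_patient = (cohort["group"] == "patient").to_numpy()
    qol = cohort["ndi_qol"].to_numpy(dtype=float)
    qpat = qol[is_patient]
    qc_all = np.zeros(len(cohort))
    if is_patient.any():
        qc_all[is_patient] = qpat - qpat.mean()
    out = {}
    tgrid = np.arange(t_points) * tr_seconds
    for s, sid in enumerate(cohort["subject_id"]):
        x = _band_signal(rng, t_points, tr_seconds, low, high, (n_rois,))
        for e, k in enumerate(effects.feature_indices):
            i, j = fmap.pair_of(int(k))
            z_target = (effects.group_shift[e] if is_patient[s] else 0.0) + \
                effects.qol_slope[e] * qc_all[s]
            r_target = float(np.clip(np.tanh(z_target), -0.999999, 0.999999))
            w = np.sqrt(abs(r_target))
            common = _band_signal(rng, t_points, tr_seconds, low, high, ())
            x[:, i] = np.sqrt(1 - w**2) * x[:, i] + w * common
            x[:, j] = np.sqrt(1 - w**2) * x[:, j] + np.sign(r_target) * w * common
        drift = drift_amplitude * rng.uniform(-1, 1, n_rois) * \
            (tgrid / tgrid[-1] - 0.5)[:, None]
        oob = outofband_amplitude * np.sin(
            2 * np.pi * 0.15 * tgrid[:, None] + rng.uniform(0, 2 * np.pi, n_rois)
        )
        out[sid] = x + drift + oob
    return out


def _write_manifest(path, seed, params: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"seed": seed, "params": params}, fh, indent=2, default=str)


def write_cohort(df: pd.DataFrame, path, seed=None, params=None) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    _write_manifest(str(path) + ".manifest.json", seed, params or {})


def write_atlas(df: pd.DataFrame, path, seed=None, params=None) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    _write_manifest(str(path) + ".manifest.json", seed, params or {})


def write_timeseries(ts: dict[str, np.ndarray], outdir, seed=None, params=None) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    for sid, mat in ts.items():
        np.savetxt(os.path.join(outdir, f"{sid}.tsv"), mat, delimiter="\t", fmt="%.10g")
    _write_manifest(os.path.join(outdir, "manifest.json"), seed, params or {})
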