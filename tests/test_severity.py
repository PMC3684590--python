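"""Score prediction, the connectivity severity index, and correlations."""

import numpy as np
import pandas as pd
import pytest

import dysconnect as d
from dysconnect.severity import (
    compute_csi,
    csi_correlations,
    edge_qol_partial_corr,
    partial_correlation,
    predict_scores,
    relative_error,
)
from dysconnect.synthetic import slope_for_correlation


class TestRelativeError:
    def test_arithmetic(self):
        assert relative_error([50.0], [50.0])[0] == 0.0
        assert np.isclose(relative_error([55.0], [50.0])[0], 0.1)

    def test_vector_matches_scalar_loop(self):
        rng = np.random.default_rng(0)
        pred = rng.uniform(10, 100, 25)
        actual = rng.uniform(10, 100, 25)
        vec = relative_error(pred, actual)
        loop = np.array([abs(p - a) / a for p, a in zip(pred, actual)])
        assert np.allclose(vec, loop)

    def test_zero_actual_flagged(self):
        err = relative_error([1.0, 2.0], [0.0, 4.0])
        assert np.isnan(err[0]) and np.isfinite(err[1])


class TestCsi:
    def test_constant_predictions(self):
        t = compute_csi([80.0, 80.0, 80.0])
        assert np.allclose(t["csi"], 1.0)

    def test_two_patient_arithmetic(self):
        t = compute_csi([60.0, 100.0])
        assert np.allclose(t["csi"], [0.75, 1.25])
        assert np.isclose(t["csi"].mean(), 1.0)

    def test_mean_is_exactly_one(self):
        rng = np.random.default_rng(1)
        t = compute_csi(rng.uniform(50, 100, 37))
        assert abs(t["csi"].mean() - 1.0) < 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_csi([80.0])
        with pytest.raises(ValueError):
            compute_csi([-1.0, 1.0])


class TestPredictScores:
    def test_linear_target_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 30))
        y = 50.0 + 4.0 * x[:, 7]  # exactly realizable from stable edge 7
        pred = predict_scores(x, y, np.array([7]), epsilon=0.001)
        assert np.nanmean(relative_error(pred, y)) < 0.05

    def test_independent_target_no_better_than_mean(self):
        worse = 0
        for s in range(10):
            rng = np.random.default_rng(50 + s)
            x = rng.standard_normal((20, 30))
            y = rng.uniform(40, 100, 20)
            pred = predict_scores(x, y, np.arange(5))
            err_model = np.nanmean(relative_error(pred, y))
            # leave-one-out mean-of-training baseline
            base = np.array([np.delete(y, k).mean() for k in range(20)])
            err_base = np.nanmean(relative_error(base, y))
            worse += err_model >= 0.8 * err_base
        assert worse >= 8

    def test_validation(self):
        x = np.zeros((4, 3))
        with pytest.raises(ValueError):
            predict_scores(x, np.arange(4.0), np.array([0]))  # < 5 patients
        x = np.random.default_rng(3).standard_normal((6, 3))
        with pytest.raises(ValueError):
            predict_scores(x, np.full(6, 2.0), np.array([0]))  # constant target
        with pytest.raises(ValueError):
            predict_scores(x, np.arange(6.0), np.array([], dtype=int))


class TestPartialCorrelation:
    def test_inert_covariate_equals_plain(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        y = 0.5 * x + rng.standard_normal(200)
        z = rng.standard_normal(200)  # unrelated to both
        r_plain = np.corrcoef(x, y)[0, 1]
        r_part, _ = partial_correlation(x, y, z)
        assert abs(r_part - r_plain) < 0.05

    def test_perfect_negative(self):
        x = np.linspace(0, 1, 30)
        r, p = partial_correlation(x, -x, np.random.default_rng(5).standard_normal(30))
        assert r < -0.999
        assert p < 1e-10

    def test_matches_bruteforce_and_pingouin(self):
        rng = np.random.default_rng(6)
        n = 60
        z = rng.standard_normal(n)
        x = 0.6 * z + rng.standard_normal(n)
        y = -0.4 * z + rng.standard_normal(n)
        r, p = partial_correlation(x, y, z)
        # brute-force residual regression oracle
        bz = np.polyfit(z, x, 1)
        rx = x - np.polyval(bz, z)
        by = np.polyfit(z, y, 1)
        ry = y - np.polyval(by, z)
        assert np.isclose(r, np.corrcoef(rx, ry)[0, 1], atol=1e-10)
        pingouin = pytest.importorskip("pingouin")
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z")
        assert np.isclose(r, ref["r"].iloc[0], atol=1e-6)
        assert np.isclose(p, ref["p_val"].iloc[0], rtol=1e-3)


class TestCsiCorrelations:
    def test_controlling_shared_factor_attenuates(self):
        cohort = d.generate_cohort(40, 2, seed=7)
        pats = cohort[cohort.group == "patient"].reset_index(drop=True)
        # a CSI proxy driven by QoL: shares the gastro factor with symptom
        table = pats.copy()
        table["csi"] = table["ndi_qol"] / table["ndi_qol"].mean()
        recs = csi_correlations(table, ("ndi_symptom", "sds", "sas"),
                                control_for=("ndi_symptom",))
        by = {r["variable"]: r for r in recs}
        assert by["ndi_symptom"]["r"] < 0
        assert abs(by["sds"]["partial_r"]) < abs(by["sds"]["r"]) + 0.05

    def test_constant_column_rejected(self):
        table = pd.DataFrame({"csi": np.ones(6), "ndi_symptom": np.arange(6.0)})
        with pytest.raises(ValueError):
            csi_correlations(table, ("ndi_symptom",))


class TestEdgeQolPartialCorr:
    def test_constant_age_equals_plain_correlation(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((30, 6))
        qol = rng.uniform(50, 100, 30)
        r = edge_qol_partial_corr(x, qol, np.full(30, 22.0))
        plain = np.array([np.corrcoef(x[:, j], qol)[0, 1] for j in range(6)])
        assert np.allclose(r, plain, atol=1e-8)

    def test_planted_negative_slopes_recovered(self):
        slope = slope_for_correlation(-0.6, 1.0, 10.17)
        eff = d.PlantedEffectMap(np.arange(5), 0.0, slope, 1.0)
        neg = 0
        for s in range(10):
            cohort = d.generate_cohort(40, 2, seed=600 + s)
            feats = d.generate_edge_data(cohort, 20, eff, seed=600 + s)
            pats = (cohort.group == "patient").to_numpy()
            r = edge_qol_partial_corr(
                feats.to_numpy()[pats], cohort.loc[pats, "ndi_qol"].to_numpy(),
                cohort.loc[pats, "age_years"].to_numpy(), indices=np.arange(5))
            neg += (r < 0).all()
        assert neg >= 9

    def test_negative_fraction_matches_planted_mix(self):
        # 65% of planted slopes negative -> recovered fraction within 10 points
        eff = d.PlantedEffectMap.default(60, n_planted=20, qol_corr=0.6,
                                         frac_negative=0.65, seed=1)
        fracs = []
        for s in range(5):
            cohort = d.generate_cohort(40, 2, seed=700 + s)
            feats = d.generate_edge_data(cohort, 60, eff, seed=700 + s)
            pats = (cohort.group == "patient").to_numpy()
            r = edge_qol_partial_corr(
                feats.to_numpy()[pats], cohort.loc[pats, "ndi_qol"].to_numpy(),
                cohort.loc[pats, "age_years"].to_numpy(),
                indices=eff.feature_indices)
            fracs.append((r < 0).mean())
        assert abs(np.mean(fracs) - 0.65) <= 0.10
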