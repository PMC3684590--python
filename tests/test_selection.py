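"""Two-filter fold-wise selection and overlap-threshold stabilization."""

import numpy as np
import pytest
from scipy import stats

import dysconnect as d
from dysconnect.selection import (
    SelectionParams,
    FeatureSubset,
    fold_subsets,
    group_ttest,
    permutation_filter,
    qol_correlation_filter,
    stabilize,
)


class TestGroupTtest:
    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((12, 50))
        b = rng.standard_normal((15, 50)) + 0.3
        t, p = group_ttest(a, b)
        ref = stats.ttest_ind(a, b, axis=0)
        assert np.allclose(t, ref.statistic, atol=1e-10)
        assert np.allclose(p, ref.pvalue, atol=1e-12)

    def test_hand_case_closed_form(self):
        # pooled t for {1,2,3} vs {2,4,6}: m1=2, m2=4, sp2=(2+8)/4=2.5
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[2.0], [4.0], [6.0]])
        t, p = group_ttest(a, b)
        expected = (2.0 - 4.0) / np.sqrt(2.5 * (1 / 3 + 1 / 3))
        assert np.isclose(t[0], expected)
        assert np.isclose(p[0], 2 * stats.t.sf(abs(expected), 4))

    def test_identical_groups_give_p_one(self):
        x = np.random.default_rng(1).standard_normal((8, 20))
        t, p = group_ttest(x, x.copy())
        assert np.allclose(t, 0.0)
        assert np.allclose(p, 1.0)

    def test_planted_large_shift_significant(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((40, 5))
        b = rng.standard_normal((40, 5))
        b[:, 2] += 3.0
        _, p = group_ttest(a, b)
        assert p[2] < 0.001

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        _, p = group_ttest(rng.standard_normal((20, 2000)),
                           rng.standard_normal((20, 2000)))
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_edge_flagged_nan(self):
        a = np.ones((5, 2))
        b = np.ones((5, 2))
        b[:, 1] = np.random.default_rng(4).standard_normal(5)
        a[:, 1] = np.random.default_rng(5).standard_normal(5)
        t, p = group_ttest(a, b)
        assert np.isnan(t[0]) and np.isfinite(t[1])

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            group_ttest(np.zeros((1, 3)), np.zeros((5, 3)))


class TestPermutationFilter:
    def test_extreme_shift_retained_at_resolution(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((15, 10))
        b = rng.standard_normal((15, 10))
        b[:, 4] += 10.0
        mask = permutation_filter(a, b, p_level=1.0 / 101, n_permutations=100, seed=0)
        assert mask[4]

    def test_constant_edge_excluded(self):
        a = np.ones((6, 3))
        b = np.ones((6, 3))
        rng = np.random.default_rng(7)
        a[:, 1:] = rng.standard_normal((6, 2))
        b[:, 1:] = rng.standard_normal((6, 2))
        mask = permutation_filter(a, b, p_level=0.5, n_permutations=100, seed=0)
        assert not mask[0]

    def test_null_retention_close_to_level(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((20, 4000))
        b = rng.standard_normal((20, 4000))
        mask = permutation_filter(a, b, p_level=0.05, n_permutations=200, seed=1)
        frac = mask.mean()
        # binomial: sd ~ sqrt(.05*.95/4000) ~ 0.0034; allow 4 sd
        assert abs(frac - 0.05) < 0.015

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((10, 200))
        b = rng.standard_normal((10, 200))
        m1 = permutation_filter(a, b, 0.1, 100, seed=5)
        m2 = permutation_filter(a, b, 0.1, 100, seed=5)
        assert np.array_equal(m1, m2)


class TestQolFilter:
    def test_exact_linear_edge_retained(self):
        qol = np.linspace(60, 95, 10)
        x = np.column_stack([2.0 * qol - 3.0, np.random.default_rng(10).standard_normal(10)])
        mask = qol_correlation_filter(x, qol, corr_alpha=1e-6)
        assert mask[0]

    def test_vacuous_alpha_retains_all(self):
        rng = np.random.default_rng(11)
        mask = qol_correlation_filter(rng.standard_normal((10, 30)),
                                      rng.uniform(50, 100, 10), corr_alpha=1.0)
        assert mask.all()

    def test_null_retention_close_to_alpha(self):
        rng = np.random.default_rng(12)
        mask = qol_correlation_filter(rng.standard_normal((40, 5000)),
                                      rng.uniform(50, 100, 40), corr_alpha=0.05)
        assert abs(mask.mean() - 0.05) < 0.015

    def test_constant_qol_rejected(self):
        with pytest.raises(ValueError):
            qol_correlation_filter(np.zeros((6, 3)), np.full(6, 80.0), 0.05)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            qol_correlation_filter(np.zeros((3, 3)), np.array([1.0, 2, 3]), 0.05)


class TestFoldSubsets:
    def test_one_subset_per_subject(self, small_cohort):
        cohort, _, features = small_cohort
        params = SelectionParams(0.05, 100, 0.05, 3)
        subs = fold_subsets(features, cohort["group"].to_numpy(),
                            cohort["ndi_qol"].to_numpy(), params)
        assert len(subs) == len(cohort)
        assert [s.fold_id for s in subs] == list(range(len(cohort)))

    def test_strong_planted_edges_recur_everywhere(self, small_cohort):
        cohort, effects, features = small_cohort
        params = SelectionParams(0.05, 200, 0.05, 3)
        subs = fold_subsets(features, cohort["group"].to_numpy(),
                            cohort["ndi_qol"].to_numpy(), params)
        rec = stabilize(subs, 0.5).recurrence
        # at least one planted edge should be selected in every single fold
        assert any(rec.get(int(k), 0) == 1.0 for k in effects.feature_indices)

    def test_selection_ignores_held_out_subject(self, small_cohort):
        cohort, _, features = small_cohort
        params = SelectionParams(0.05, 100, 0.05, 3)
        subs = fold_subsets(features, cohort["group"].to_numpy(),
                            cohort["ndi_qol"].to_numpy(), params)
        corrupted = features.copy()
        corrupted.iloc[0] = 1e6  # absurd held-out subject
        subs2 = fold_subsets(corrupted, cohort["group"].to_numpy(),
                             cohort["ndi_qol"].to_numpy(), params)
        assert np.array_equal(subs[0].indices, subs2[0].indices)

    def test_vanishing_level_empties_subsets(self, small_cohort):
        cohort, _, features = small_cohort
        params = SelectionParams(1e-5, 100, 0.05, 3)  # below 1/(n_perm+1)
        subs = fold_subsets(features, cohort["group"].to_numpy(),
                            cohort["ndi_qol"].to_numpy(), params)
        assert all(len(s.indices) == 0 for s in subs)

    def test_tiny_group_rejected(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((6, 10))
        labels = np.array([True] * 4 + [False] * 2)
        with pytest.raises(ValueError):
            fold_subsets(x, labels, rng.uniform(0, 1, 6), SelectionParams(seed=0))


class TestStabilize:
    def _subsets(self, membership):
        return [FeatureSubset(i, np.flatnonzero(row))
                for i, row in enumerate(membership)]

    def test_threshold_arithmetic(self):
        member = np.zeros((80, 2), dtype=bool)
        member[:71, 0] = True  # recurrence 71/80 = 0.8875
        member[:, 1] = True
        subs = self._subsets(member)
        assert 0 not in stabilize(subs, 0.90).indices
        assert 0 in stabilize(subs, 0.85).indices
        assert np.isclose(stabilize(subs, 0.5).recurrence[0], 0.8875)

    def test_tau_one_is_intersection(self):
        rng = np.random.default_rng(14)
        member = rng.random((10, 40)) < 0.7
        subs = self._subsets(member)
        expected = np.flatnonzero(member.all(axis=0))
        assert np.array_equal(stabilize(subs, 1.0).indices, expected)

    def test_monotone_in_tau_bruteforce(self):
        rng = np.random.default_rng(15)
        member = rng.random((20, 100)) < 0.8
        subs = self._subsets(member)
        sizes = [len(stabilize(subs, t)) for t in (1.0, 0.95, 0.90, 0.85)]
        assert sizes == sorted(sizes)
        # brute-force counting oracle for tau = 0.9
        counts = member.sum(axis=0)
        assert np.array_equal(stabilize(subs, 0.9).indices,
                              np.flatnonzero(counts / 20 >= 0.9))

    def test_validation(self):
        with pytest.raises(ValueError):
            stabilize([], 0.9)
        with pytest.raises(ValueError):
            stabilize(self._subsets(np.ones((2, 2), bool)), 0.0)


def test_params_validation():
    with pytest.raises(ValueError):
        SelectionParams(p_level=0.0)
    with pytest.raises(ValueError):
        SelectionParams(n_permutations=50)
    with pytest.raises(ValueError):
        SelectionParams(corr_alpha=1.5)
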