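"""Permutation inference, score tests, t-test baseline, overlap ratios."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from t3brain.feature_tensor import METRIC_ORDER, FeatureTensor
from t3brain.inference import (
    overlap_ratio,
    paired_ttest_features,
    permutation_test,
    score_condition_test,
)
from t3brain.synthetic import TensorSynthSpec, generate_feature_tensor
from t3brain.t3clus import ScoreMatrix, TuckerConfig, build_indicator, component_scores, fit


def _tensor_from_array(X):
    I, J, K = X.shape
    obs = [(f"s{i:03d}", c) for i in range(I // 2) for c in ("rest", "meditation")]
    return FeatureTensor(X, obs, [f"R{j:03d}" for j in range(J)], list(METRIC_ORDER[:K]))


class TestPermutationTest:
    def test_minimum_p_and_reproducibility(self):
        spec = TensorSynthSpec(n_subjects=8, J=10, delta=4.0, sigma=0.1, seed=2)
        tensor, truth = generate_feature_tensor(spec)
        a = permutation_test(tensor, n_perm=99, seed=5)
        b = permutation_test(tensor, n_perm=99, seed=5)
        assert np.array_equal(a.region_pvalues, b.region_pvalues)
        assert a.region_pvalues.min() >= 1 / 100
        assert np.all(a.region_pvalues <= 1)

    def test_power_on_strong_planted_effect(self):
        from t3brain.feature_tensor import standardize

        spec = TensorSynthSpec(n_subjects=29, J=116, delta=5.0, sigma=0.5, seed=7)
        tensor, truth = generate_feature_tensor(spec)
        tensor = standardize(tensor)
        res = permutation_test(tensor, n_perm=499, seed=1)
        planted = [tensor.region_names[j] for j in truth.planted_region_set]
        for name, p in zip(res.region_names, res.region_pvalues):
            if name in planted:
                assert p <= 0.01
        assert res.metric_pvalues[truth.planted_metric_index] <= 0.01
        assert set(planted) <= set(res.significant_regions)

    def test_free_scheme_and_validation(self):
        spec = TensorSynthSpec(n_subjects=6, J=10, delta=2.0, sigma=0.5, seed=3)
        tensor, _ = generate_feature_tensor(spec)
        res = permutation_test(tensor, n_perm=49, scheme="free", seed=2)
        assert res.scheme == "free"
        with pytest.raises(ValueError):
            permutation_test(tensor, n_perm=0)
        with pytest.raises(ValueError):
            permutation_test(tensor, n_perm=10, scheme="bogus")

    def test_sign_convention_invariance(self):
        # flipping the sign of the whole array flips loadings but not |.|,
        # so the p-values are unchanged
        spec = TensorSynthSpec(n_subjects=6, J=10, delta=2.0, sigma=0.5, seed=9)
        tensor, _ = generate_feature_tensor(spec)
        flipped = _tensor_from_array(-tensor.X)
        a = permutation_test(tensor, n_perm=99, seed=4)
        b = permutation_test(flipped, n_perm=99, seed=4)
        assert a.region_pvalues == pytest.approx(b.region_pvalues)


class TestScoreConditionTest:
    def test_identical_scores_null(self):
        raw = np.tile(np.arange(8.0)[:, None], (1, 2))
        raw = np.vstack([raw, raw])  # same scores in both conditions per subject
        obs = [(f"s{i}", "rest") for i in range(8)] + [(f"s{i}", "meditation") for i in range(8)]
        sm = ScoreMatrix(raw, raw)
        table = score_condition_test(sm, obs)
        assert (table.t == 0).all() and (table.p == 1).all()

    def test_hand_computed_paired_t(self):
        # 5 subjects, differences d = (1, 2, 3, 4, 5): t = mean/(sd/sqrt(5))
        rest = np.zeros((5, 1))
        med = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        raw = np.vstack([rest, med])
        obs = [(f"s{i}", "rest") for i in range(5)] + [(f"s{i}", "meditation") for i in range(5)]
        table = score_condition_test(ScoreMatrix(raw, raw), obs)
        d = med.ravel()
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert table.t[0] == pytest.approx(t_expected)
        assert table.df[0] == 4

    def test_planted_effect_separates_first_component_only(self):
        from t3brain.feature_tensor import standardize

        hits = 0
        for rep in range(10):
            spec = TensorSynthSpec(n_subjects=15, J=30, delta=5.0, sigma=0.3, seed=50 + rep)
            tensor, _ = generate_feature_tensor(spec)
            tensor = standardize(tensor)
            U = build_indicator(tensor.labels, 2)
            res = fit(tensor, U)
            table = score_condition_test(component_scores(res, tensor, U), tensor.observation_index)
            if table.p[0] < 0.001 and table.p[1] > 0.05:
                hits += 1
        assert hits >= 9


class TestPairedTTestBaseline:
    def test_bh_step_up_hand_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        q = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_identical_conditions_all_q_one(self, rng):
        half = rng.standard_normal((4, 6, 4))
        X = np.empty((8, 6, 4))
        X[0::2] = half  # rest
        X[1::2] = half  # meditation identical
        tensor = _tensor_from_array(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            table = paired_ttest_features(tensor)
        assert (table.q == 1.0).all()
        assert not table.significant.any()

    def test_matches_scipy_on_random_data(self, rng):
        from scipy import stats

        X = rng.standard_normal((12, 5, 4))
        tensor = _tensor_from_array(X)
        table = paired_ttest_features(tensor)
        idx = {sc: i for i, sc in enumerate(tensor.observation_index)}
        subs = sorted({s for s, _ in tensor.observation_index})
        j, k = 2, 1
        med = np.array([X[idx[(s, "meditation")], j, k] for s in subs])
        rest = np.array([X[idx[(s, "rest")], j, k] for s in subs])
        t, p = stats.ttest_rel(med, rest)
        row = table[(table.region == tensor.region_names[j]) & (table.metric == tensor.metric_names[k])]
        assert row.t.iloc[0] == pytest.approx(t)
        assert row.p.iloc[0] == pytest.approx(p)
        assert (table.q >= table.p - 1e-12).all()


class TestOverlapRatio:
    def test_ratios(self):
        costs = [round(0.050 + 0.025 * i, 3) for i in range(19)]
        sets = {c: {"always"} for c in costs}
        higher = [c for c in costs if c >= 0.250]
        for i, c in enumerate(higher):
            if i > 0:  # selected at 10 of the 11 higher costs
                sets[c] = sets[c] | {"high_only"}
        sets[costs[0]] |= {"once"}
        report = overlap_ratio(sets, costs).set_index("region")
        assert report.loc["always", "ratio"] == pytest.approx(1.0)
        assert report.loc["high_only", "higher_ratio"] == pytest.approx(10 / 11)
        assert round(report.loc["high_only", "higher_ratio"], 2) == 0.91
        assert report.loc["once", "ratio"] == pytest.approx(1 / 19)
        assert report.loc["once", "lower_ratio"] == pytest.approx(1 / 8)
        assert report.loc["once", "higher_ratio"] == 0.0

    def test_missing_cost_rejected(self):
        with pytest.raises(ValueError, match="0.1"):
            overlap_ratio({0.05: set()}, [0.05, 0.1])
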