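"""Risk-model scores, time-dependent AUC, bootstrap, sensitivity filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mirtraject as mt
from mirtraject.errors import (
    ConfigurationError,
    EstimationError,
    InsufficientDataError,
)
from mirtraject.prediction import MODEL_IDS, fit_all_models


class TestModelSpecs:
    def test_nesting(self):
        feats = {m: set(mt.model_features(m, ["miR-a", "miR-b"])) for m in MODEL_IDS}
        assert feats[1] < feats[2] < feats[4]
        assert feats[1] < feats[3] < feats[4]
        assert feats[4] == feats[2] | feats[3]

    def test_unknown_model(self):
        with pytest.raises(ConfigurationError):
            mt.model_features(5, [])


def _auc_brute_force(cases, controls):
    wins = 0.0
    for c in cases:
        for k in controls:
            wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / (len(cases) * len(controls))


class TestMannWhitneyAuc:
    def test_perfect_separation(self):
        assert mt.mann_whitney_auc([3, 4], [1, 2]) == 1.0

    def test_worked_example(self):
        assert mt.mann_whitney_auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_ties_count_half(self):
        assert mt.mann_whitney_auc([1.0], [1.0]) == 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_and_scipy(self, seed):
        from scipy import stats

        rng = np.random.default_rng(seed)
        cases = rng.integers(0, 8, size=int(rng.integers(1, 20))).astype(float)
        controls = rng.integers(0, 8, size=int(rng.integers(1, 20))).astype(float)
        auc = mt.mann_whitney_auc(cases, controls)
        assert auc == _auc_brute_force(cases, controls)
        u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (len(cases) * len(controls)))

    def test_rank_sum_path_equals_brute_force(self):
        # large inputs take the O(n log n) rank-sum identity
        rng = np.random.default_rng(7)
        cases = rng.integers(0, 40, size=150).astype(float)
        controls = rng.integers(0, 40, size=120).astype(float)
        assert mt.mann_whitney_auc(cases, controls) == pytest.approx(
            _auc_brute_force(cases, controls), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        cases = rng.normal(size=10)
        controls = rng.normal(size=12)
        auc = mt.mann_whitney_auc(cases, controls)
        assert mt.mann_whitney_auc(np.exp(cases), np.exp(controls)) == auc


class TestTimeDependentAuc:
    def test_cumulative_restriction(self, small_normed):
        manifest, normed, _ = small_normed
        scores = pd.Series(
            np.arange(len(manifest), dtype=float), index=manifest["sample_id"]
        )
        point = mt.time_dependent_auc(scores, manifest, horizon=5.0)
        eligible = manifest.drop_duplicates("pair_id")
        expected_n = (eligible["lead_time_years"] <= 5.0).sum()
        assert point.n_case_pairs == expected_n

    def test_no_eligible_pairs(self, small_normed):
        manifest, _, _ = small_normed
        scores = pd.Series(0.0, index=manifest["sample_id"])
        with pytest.raises(InsufficientDataError):
            mt.time_dependent_auc(scores, manifest, horizon=0.001)

    def test_nonpositive_horizon(self, small_normed):
        manifest, _, _ = small_normed
        scores = pd.Series(0.0, index=manifest["sample_id"])
        with pytest.raises(ConfigurationError):
            mt.time_dependent_auc(scores, manifest, horizon=0.0)


class TestFitRiskScore:
    def test_separation_flagged(self, small_cohort):
        manifest, _, _ = small_cohort
        features = pd.DataFrame(
            {"x": (manifest["role"] == "case").astype(float).to_numpy()},
            index=manifest["sample_id"],
        )
        scores, fit = mt.fit_risk_score(features, manifest, ["x"])
        assert not fit.converged

    def test_null_feature_near_chance(self, small_cohort):
        manifest, _, _ = small_cohort
        rng = np.random.default_rng(8)
        features = pd.DataFrame(
            {"x": rng.normal(size=len(manifest))}, index=manifest["sample_id"]
        )
        scores, fit = mt.fit_risk_score(features, manifest, ["x"])
        auc = mt.time_dependent_auc(scores, manifest, horizon=25.0).auc
        assert abs(auc - 0.5) < 0.1

    def test_ca199_coefficient_sign_recovered(self, small_normed):
        manifest, normed, _ = small_normed
        features = mt.build_feature_table(normed, manifest, [])
        _, fit = mt.fit_risk_score(
            features, manifest, mt.model_features(2, [])
        )
        assert fit.beta[fit.names.index("log_ca199")] > 0


class TestApparentCurve:
    def test_one_row_per_model_per_horizon(self, small_normed, signal_panel):
        manifest, normed, _ = small_normed
        mirnas = list(signal_panel)[:4]
        features = mt.build_feature_table(normed, manifest, mirnas)
        grid = mt.auc_curve(features, manifest, mirnas, horizons=[2, 5, 10])
        assert len(grid) == 4 * 3
        assert set(grid["model"]) == set(MODEL_IDS)

    def test_model4_dominates_nested_models_in_sample(
        self, small_normed, signal_panel
    ):
        """With every model ML-refitted on the same restricted pairs, the
        richest model's in-sample AUC is at least each nested model's
        (frozen fixture large enough for interior ML solutions)."""
        cfg = mt.GeneratorConfig.from_dict({"scale": 0.5}, seed=11)
        manifest, matrix, _ = mt.generate_cohort(cfg)
        normed, _ = mt.normalize_pipeline(matrix)
        mirnas = list(signal_panel)
        features = mt.build_feature_table(normed, manifest, mirnas)
        for horizon in (5.0, 10.0):
            eligible = manifest[
                manifest["lead_time_years"].astype(float) <= horizon
            ]
            fits = fit_all_models(features, eligible, mirnas)
            aucs = {
                m: mt.time_dependent_auc(scores, eligible, horizon).auc
                for m, (scores, _) in fits.items()
            }
            for nested in (1, 2, 3):
                assert aucs[4] >= aucs[nested] - 1e-6


class TestBootstrap:
    def test_deterministic_given_seed(self, small_normed, signal_panel):
        manifest, normed, _ = small_normed
        mirnas = list(signal_panel)[:3]
        features = mt.build_feature_table(normed, manifest, mirnas)
        kwargs = dict(horizons=[5, 10], models=[1, 2], n_boot=50, seed=9)
        a = mt.bootstrap_validate(features, manifest, mirnas, **kwargs)
        b = mt.bootstrap_validate(features, manifest, mirnas, **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_b_below_minimum_rejected(self, small_normed):
        manifest, normed, _ = small_normed
        features = mt.build_feature_table(normed, manifest, [])
        with pytest.raises(ConfigurationError):
            mt.bootstrap_validate(features, manifest, [], n_boot=10)

    def test_oob_mean_below_apparent_for_largest_model(
        self, small_normed, signal_panel
    ):
        """Optimism is non-negative on average: out-of-bag AUC of the full
        model does not exceed its apparent AUC (frozen fixture, t=10)."""
        manifest, normed, _ = small_normed
        mirnas = list(signal_panel)
        features = mt.build_feature_table(normed, manifest, mirnas)
        apparent = mt.auc_curve(features, manifest, mirnas, horizons=[10],
                                models=[4])
        boot = mt.bootstrap_validate(
            features, manifest, mirnas, horizons=[10], models=[4],
            n_boot=60, seed=3,
        )
        assert boot["auc"].iloc[0] <= apparent["auc"].iloc[0] + 0.01
        assert boot["ci_low"].iloc[0] <= boot["auc"].iloc[0] <= boot["ci_high"].iloc[0]


class TestCa199Contribution:
    def test_zero_effect_near_zero_contribution(self):
        cfg = mt.GeneratorConfig.from_dict(
            {"scale": 0.3, "ca199": {"gamma": 0.0}}, seed=6
        )
        manifest, matrix, _ = mt.generate_cohort(cfg)
        normed, _ = mt.normalize_pipeline(matrix)
        mirnas = [p.probe_id for p in mt.default_trajectory_panel()]
        features = mt.build_feature_table(normed, manifest, mirnas)
        out = mt.ca199_contribution(features, manifest, mirnas, horizon=3.0)
        assert abs(out["fraction"]) < 0.15

    def test_ca199_only_signal_gives_full_contribution(self):
        cfg = mt.GeneratorConfig.from_dict(
            {"scale": 0.3, "panel": "null", "smoking_case_or": 1.0,
             "diabetes_case_or": 1.0},
            seed=6,
        )
        manifest, matrix, _ = mt.generate_cohort(cfg)
        normed, _ = mt.normalize_pipeline(matrix)
        features = mt.build_feature_table(normed, manifest, [])
        out = mt.ca199_contribution(features, manifest, [], horizon=2.0)
        assert out["fraction"] > 0.8

    def test_definition_string_attached(self, small_normed):
        manifest, normed, _ = small_normed
        features = mt.build_feature_table(normed, manifest, [])
        out = mt.ca199_contribution(features, manifest, [], horizon=2.0)
        assert "AUC" in out["definition"]


class TestSensitivityFilters:
    def test_min_lead_strict_inequality(self, small_cohort):
        manifest, _, _ = small_cohort
        toy = manifest[manifest["pair_id"].isin(
            manifest["pair_id"].unique()[:3]
        )].copy()
        toy.loc[:, "lead_time_years"] = np.repeat([0.5, 1.0, 1.5], 2)
        kept = mt.sensitivity_filters(toy, "min_lead_1y")
        assert set(kept["lead_time_years"]) == {1.5}

    def test_none_is_identity(self, small_cohort):
        manifest, _, _ = small_cohort
        pd.testing.assert_frame_equal(
            mt.sensitivity_filters(manifest, "none"), manifest
        )

    def test_early_stage_matches_truth(self, small_cohort):
        manifest, _, _ = small_cohort
        kept = mt.sensitivity_filters(manifest, "early_stage")
        cases = manifest[manifest["role"] == "case"]
        expected = (cases["stage"].isin(["I", "IIA"])).sum()
        assert kept["pair_id"].nunique() == expected
        assert kept.groupby("pair_id")["role"].nunique().eq(2).all()

    def test_missing_stage_column(self, small_cohort):
        manifest, _, _ = small_cohort
        with pytest.raises(ConfigurationError):
            mt.sensitivity_filters(manifest.drop(columns="stage"), "early_stage")

    def test_unknown_mode(self, small_cohort):
        manifest, _, _ = small_cohort
        with pytest.raises(ConfigurationError):
            mt.sensitivity_filters(manifest, "bogus")
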