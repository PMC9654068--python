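import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from glucolens import explain, modeling
from glucolens.explain import (
    GROUPS,
    PeakSet,
    ShapExplanation,
    UnmappedFeatureError,
    compute_attributions,
    feature_group,
    find_peaks_q3iqr,
    overall_importance,
    peak_feature_frequency,
)
from glucolens.features import GLUCOSE_FEATURES
from oracles import peaks_bruteforce, quantile_type7, shapley_bruteforce


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(12)
    n, p = 500, 6
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    X.iloc[::9, 3] = np.nan
    y = pd.Series(1.6 + 0.25 * X["f0"].fillna(0.0) + 0.1 * (X["f1"] > 0) + 0.05 * rng.normal(size=n))
    bundle = modeling.fit(X, y, "glucose_regression", rounds=80, seed=4)
    return bundle, X


class TestAttributions:
    def test_local_accuracy_machine_precision(self, fitted):
        bundle, X = fitted
        expl = compute_attributions(bundle, X)
        err = np.abs(expl.base_value + expl.values.sum(axis=1) - expl.raw_margin)
        assert err.max() < 1e-10

    def test_margin_agrees_with_booster(self, fitted):
        bundle, X = fitted
        expl = compute_attributions(bundle, X)
        d = xgb.DMatrix(X.to_numpy(float), feature_names=list(X.columns), missing=np.nan)
        ref = bundle.booster.predict(d, output_margin=True)
        np.testing.assert_allclose(expl.raw_margin, ref, atol=1e-4)

    def test_agrees_with_independent_implementation(self, fitted):
        # xgboost ships its own tree-path-dependent Shapley implementation
        bundle, X = fitted
        expl = compute_attributions(bundle, X)
        d = xgb.DMatrix(X.to_numpy(float), feature_names=list(X.columns), missing=np.nan)
        ref = bundle.booster.predict(d, pred_contribs=True)
        np.testing.assert_allclose(expl.values, ref[:, :-1], atol=1e-4)
        assert expl.base_value == pytest.approx(float(ref[0, -1]), abs=1e-4)

    def test_matches_bruteforce_subset_enumeration(self):
        # small forest over 4 features: exact Shapley by enumerating all
        # feature subsets with cover-weighted expectations
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        y = pd.Series(0.5 * X["a"] + 0.3 * (X["b"] > 0) - 0.2 * X["c"] + 0.1 * rng.normal(size=200))
        bundle = modeling.fit(X, y, "glucose_regression", params={"max_depth": 3, "eta": 0.3}, rounds=5, seed=0)
        expl = compute_attributions(bundle, X.iloc[:10])
        trees = explain._extract_trees(bundle)[:8]
        Xv = X.to_numpy(np.float32).astype(np.float64)
        for r in range(10):
            ref = shapley_bruteforce(trees, Xv[r], 4)
            np.testing.assert_allclose(expl.values[r], ref, atol=1e-9, err_msg=f"row {r}")

    def test_depth_one_tree_hand_case(self):
        # single stump on a binary feature: each side's contribution is the
        # leaf deviation from the cover-weighted mean
        X = pd.DataFrame({"b": np.r_[np.zeros(30), np.ones(70)], "z": np.zeros(100)})
        y = pd.Series(np.r_[np.full(30, 1.0), np.full(70, 3.0)])
        bundle = modeling.fit(
            X, y, "glucose_regression",
            params={"max_depth": 1, "eta": 1.0, "min_child_weight": 0.0}, rounds=1, seed=0,
        )
        expl = compute_attributions(bundle, X.iloc[[0, 99]])
        left, right, feat, thresh, defleft, value, cover, roots, _, bs = explain._extract_trees(bundle)
        v_left, v_right = value[left[0]], value[right[0]]
        c_left, c_right = cover[left[0]], cover[right[0]]
        mean = (c_left * v_left + c_right * v_right) / (c_left + c_right)
        assert expl.values[0, 0] == pytest.approx(v_left - mean, abs=1e-12)
        assert expl.values[1, 0] == pytest.approx(v_right - mean, abs=1e-12)
        assert expl.values[:, 1] == pytest.approx(0.0)  # never-split feature

    def test_constant_model_all_zero(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        y = pd.Series(np.full(20, 2.0))
        bundle = modeling.fit(X, y, "glucose_regression", rounds=3, seed=0)
        expl = compute_attributions(bundle, X)
        np.testing.assert_allclose(expl.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(expl.raw_margin, expl.base_value, atol=1e-12)

    def test_never_split_feature_zero_everywhere(self, fitted):
        bundle, X = fitted
        X2 = X.assign(dummy=1.0)
        bundle2 = modeling.fit(X2, pd.Series(bundle.booster.predict(
            xgb.DMatrix(X.to_numpy(float), feature_names=list(X.columns), missing=np.nan)
        )), "glucose_regression", rounds=40, seed=1)
        expl = compute_attributions(bundle2, X2)
        assert np.abs(expl.values[:, -1]).max() == 0.0

    def test_duplicated_feature_splits_contribution(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("abc"))
        y = pd.Series(X["a"] * 0.5 + 0.05 * rng.normal(size=400))
        b1 = modeling.fit(X, y, "glucose_regression", rounds=40, seed=2)
        w1 = np.abs(compute_attributions(b1, X).values[:, 0]).mean()
        X2 = X.assign(a2=X["a"])
        b2 = modeling.fit(X2, y, "glucose_regression", rounds=40, seed=2)
        e2 = compute_attributions(b2, X2)
        names = e2.feature_names
        w2 = (
            np.abs(e2.values[:, names.index("a")]).mean()
            + np.abs(e2.values[:, names.index("a2")]).mean()
        )
        assert w2 == pytest.approx(w1, rel=0.05)

    def test_non_tree_input_rejected(self):
        with pytest.raises(explain.UnsupportedModelError):
            compute_attributions(object(), pd.DataFrame({"a": [1.0]}))


class TestImportance:
    def make_expl(self, values, names):
        values = np.asarray(values, dtype=float)
        return ShapExplanation(values, 0.0, names, values.sum(axis=1))

    def test_single_active_feature_takes_full_weight(self):
        expl = self.make_expl([[0.0, 0.3], [0.0, -0.1]], ["acn_30m_sum", "sleep_duration"])
        _, groups = overall_importance(expl)
        assert groups.set_index("group").loc["sleep", "percent"] == pytest.approx(100.0)

    def test_mean_of_absolutes_not_absolute_of_mean(self):
        expl = self.make_expl([[0.4], [-0.4]], ["sleep_duration"])
        per_feature, _ = overall_importance(expl)
        assert per_feature.loc[0, "weight"] == pytest.approx(0.4)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        names = GLUCOSE_FEATURES + ["subj_S01", "subj_S02"]
        expl = self.make_expl(rng.normal(size=(50, len(names))), names)
        _, groups = overall_importance(expl)
        assert groups["percent"].sum() == pytest.approx(100.0, abs=0.1)
        assert set(groups["group"]) == set(GROUPS)

    def test_unmapped_feature_rejected(self):
        expl = self.make_expl([[0.1]], ["mystery_column"])
        with pytest.raises(UnmappedFeatureError):
            overall_importance(expl)

    @pytest.mark.parametrize(
        "name,group",
        [
            ("ee_24h_sum", "cardiometabolic"),
            ("ahr_30m_mean", "cardiometabolic"),
            ("acn_3h_sum", "activity_short_term"),
            ("acn_8h_sum", "activity_long_term"),
            ("kcal_carb_90m_sum", "nutrition_short_term"),
            ("frac_fat_24h_mean", "nutrition_long_term"),
            ("sleep_duration", "sleep"),
            ("deep_sleep_duration", "sleep"),
            ("subj_S07", "subject"),
        ],
    )
    def test_group_mapping(self, name, group):
        assert feature_group(name) == group

    def test_every_engineered_feature_is_mapped(self):
        for name in GLUCOSE_FEATURES:
            assert feature_group(name) in GROUPS


class TestPeaks:
    def test_monotone_series_has_no_peaks(self):
        ps = find_peaks_q3iqr(np.linspace(4, 9, 50), "S01")
        assert ps.n_peaks == 0

    def test_single_spike_with_zero_iqr(self):
        v = np.array([5, 5, 5, 5, 5, 5, 5, 5, 9, 5, 5, 5], dtype=float)
        ps = find_peaks_q3iqr(v, "S01")
        assert ps.threshold == pytest.approx(5.0)
        assert ps.peak_positions.tolist() == [8]

    def test_plateau_takes_first_index(self):
        # mostly-flat series: Q1 = Q3 = 4, threshold 4; plateau peak at its start
        v = np.array([4, 4, 4, 4, 4, 4, 4, 4, 9, 9, 4, 4, 4, 4], dtype=float)
        ps = find_peaks_q3iqr(v, "S01")
        assert ps.peak_positions.tolist() == [8]

    def test_exclusion_below_ten_peaks(self):
        rng = np.random.default_rng(0)
        v = np.full(200, 5.0)
        v[10:100:10] = 9.0  # 9 spikes
        ps = find_peaks_q3iqr(v, "S01")
        assert ps.n_peaks == 9 and ps.excluded
        v[110] = 9.0
        assert not find_peaks_q3iqr(v, "S01").n_peaks < 10

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            find_peaks_q3iqr(np.array([5.0, 6.0]), "S01")

    def test_matches_bruteforce_oracle_on_random_series(self):
        rng = np.random.default_rng(77)
        for trial in range(500):
            n = int(rng.integers(10, 120))
            v = np.round(rng.uniform(3, 10, n), 1)  # rounding makes plateaus likely
            ps = find_peaks_q3iqr(v, "S01")
            thr, ref = peaks_bruteforce(v)
            assert ps.threshold == pytest.approx(thr, abs=1e-12), trial
            assert ps.peak_positions.tolist() == ref, trial

    def test_quantiles_are_type7(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(3, 9, 37)
        ps = find_peaks_q3iqr(v, "S01")
        s = np.sort(v)
        assert ps.q3 == pytest.approx(quantile_type7(s, 0.75), abs=1e-12)
        assert ps.q1 == pytest.approx(quantile_type7(s, 0.25), abs=1e-12)


class TestPeakFrequency:
    def make_expl(self, values, names):
        values = np.asarray(values, dtype=float)
        return ShapExplanation(values, 0.0, names, values.sum(axis=1))

    def test_dominant_feature_counted_once_per_peak(self):
        expl = self.make_expl([[2.0, 0.1, 0.0]], ["a_30m_sum", "b_30m_sum", "c_30m_sum"])
        out = peak_feature_frequency(expl, {"S01": np.array([0])}, k=1)
        assert out.loc[0, "feature"] == "a_30m_sum" and out.loc[0, "count"] == 1

    def test_counts_sum_to_k_times_n_peaks(self):
        rng = np.random.default_rng(5)
        names = [f"f{i}_30m_sum" for i in range(8)]
        expl = self.make_expl(rng.normal(size=(30, 8)), names)
        rows = {"S01": np.arange(12), "S02": np.arange(12, 30)}
        out = peak_feature_frequency(expl, rows, k=5)
        sums = out.groupby("subject_id")["count"].sum()
        assert sums["S01"] == 5 * 12 and sums["S02"] == 5 * 18

    def test_excluded_subject_omitted(self):
        expl = self.make_expl(np.ones((4, 6)), [f"f{i}" for i in range(6)])
        sets = {
            "S01": PeakSet("S01", 7.0, 5.0, 6.0, np.array([0]), 1, excluded=True),
            "S02": PeakSet("S02", 7.0, 5.0, 6.0, np.arange(3), 3, excluded=False),
        }
        out = peak_feature_frequency(expl, {"S01": np.array([0]), "S02": np.arange(1, 4)}, sets, k=2)
        assert set(out["subject_id"]) == {"S02"}

    def test_ties_break_by_column_order(self):
        expl = self.make_expl([[1.0, 1.0, 1.0]], ["c1", "c2", "c3"])
        out = peak_feature_frequency(expl, {"S01": np.array([0])}, k=2)
        assert sorted(out["feature"]) == ["c1", "c2"]
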