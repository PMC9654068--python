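import numpy as np
import pandas as pd
import pytest

from glucolens import preprocess
from glucolens.preprocess import (
    aggregate_meals,
    align_activity,
    join_sleep,
    select_stretches,
    split_glucose,
    split_mealdetect,
)
from conftest import EPOCH, make_aligned
from oracles import stretches_bruteforce


def diary(rows):
    return pd.DataFrame(rows, columns=["subject_id", "timestamp", "carb_g", "fat_g", "protein_g"])


def ts(s):
    return pd.Timestamp(f"2022-03-01 {s}")


class TestAggregateMeals:
    def test_items_within_15min_merge(self):
        d = diary([("S01", ts("12:00"), 10, 0, 0), ("S01", ts("12:10"), 20, 5, 5)])
        out = aggregate_meals(d)
        assert len(out) == 1
        assert out.loc[0, "timestamp"] == ts("12:00")
        assert out.loc[0, "kcal_carb"] == pytest.approx(4 * 30)

    def test_items_beyond_15min_stay_separate(self):
        d = diary([("S01", ts("12:00"), 10, 0, 0), ("S01", ts("12:20"), 20, 0, 0)])
        assert len(aggregate_meals(d)) == 2

    def test_transitive_chaining(self):
        d = diary(
            [("S01", ts("12:00"), 10, 0, 0), ("S01", ts("12:14"), 10, 0, 0),
             ("S01", ts("12:28"), 10, 0, 0)]
        )
        out = aggregate_meals(d)
        assert len(out) == 1 and out.loc[0, "kcal_carb"] == pytest.approx(120)

    def test_atwater_arithmetic_and_fractions(self):
        out = aggregate_meals(diary([("S01", ts("08:00"), 10, 0, 0)]))
        assert out.loc[0, "kcal_total"] == pytest.approx(40.0)
        assert out.loc[0, "frac_carb"] == pytest.approx(1.0)
        out2 = aggregate_meals(diary([("S01", ts("08:00"), 10, 10, 10)]))
        assert out2.loc[0, "kcal_total"] == pytest.approx(40 + 90 + 40)
        assert out2.loc[0, ["frac_carb", "frac_fat", "frac_protein"]].sum() == pytest.approx(1.0)

    def test_zero_calorie_event_has_zero_fractions(self):
        out = aggregate_meals(diary([("S01", ts("08:00"), 0, 0, 0)]))
        assert (out.loc[0, ["frac_carb", "frac_fat", "frac_protein"]] == 0).all()

    def test_negative_grams_rejected(self):
        with pytest.raises(ValueError):
            aggregate_meals(diary([("S01", ts("08:00"), -1, 0, 0)]))

    def test_calorie_conservation_and_idempotence(self):
        rng = np.random.default_rng(3)
        rows = [
            ("S%02d" % rng.integers(1, 4), EPOCH + pd.Timedelta(minutes=int(t)),
             float(rng.uniform(0, 80)), float(rng.uniform(0, 40)), float(rng.uniform(0, 40)))
            for t in np.sort(rng.uniform(0, 3 * 1440, 60))
        ]
        d = diary(rows)
        out = aggregate_meals(d)
        expected = 4 * d["carb_g"].sum() + 9 * d["fat_g"].sum() + 4 * d["protein_g"].sum()
        assert out["kcal_total"].sum() == pytest.approx(expected, abs=1e-9)
        # re-aggregating the events (as gram items) must change nothing
        back = out.assign(
            carb_g=out["kcal_carb"] / 4, fat_g=out["kcal_fat"] / 9, protein_g=out["kcal_protein"] / 4
        )[["subject_id", "timestamp", "carb_g", "fat_g", "protein_g"]]
        again = aggregate_meals(back)
        pd.testing.assert_frame_equal(
            again.sort_values(["subject_id", "timestamp"], ignore_index=True),
            out.sort_values(["subject_id", "timestamp"], ignore_index=True),
            check_exact=False,
        )


class TestAlignActivity:
    def test_sum_and_mean_aggregation(self):
        grid = pd.date_range(EPOCH, periods=2, freq="15min")
        act = pd.DataFrame(
            {
                "timestamp": [EPOCH + pd.Timedelta(minutes=m) for m in (0, 5, 10, 20)],
                "energy_expenditure": [1.0, 1.0, 1.0, 2.0],
                "acceleration": [10.0, 20.0, 30.0, 5.0],
                "heart_rate": [60.0, 70.0, 65.0, 80.0],
            }
        )
        out = align_activity(act, grid, pd.Timedelta(minutes=15))
        assert out["energy_expenditure"].tolist() == [3.0, 2.0]
        assert out["acceleration"].tolist() == [60.0, 5.0]
        assert out["heart_rate"].tolist() == [65.0, 80.0]
        assert out["activity_avail"].all()

    def test_empty_intervals_flagged_missing(self):
        grid = pd.date_range(EPOCH, periods=3, freq="15min")
        act = pd.DataFrame(
            {
                "timestamp": [EPOCH + pd.Timedelta(minutes=40)],
                "energy_expenditure": [2.0], "acceleration": [1.0], "heart_rate": [70.0],
            }
        )
        out = align_activity(act, grid, pd.Timedelta(minutes=15))
        assert out["activity_avail"].tolist() == [False, False, True]
        assert np.isnan(out["heart_rate"].iloc[0])

    def test_matches_bruteforce_on_random_placement(self):
        rng = np.random.default_rng(7)
        grid = pd.date_range(EPOCH, periods=20, freq="15min")
        t_min = np.sort(rng.uniform(0, 20 * 15, 200))
        act = pd.DataFrame(
            {
                "timestamp": EPOCH + pd.to_timedelta(t_min, unit="m"),
                "energy_expenditure": rng.uniform(0, 5, 200),
                "acceleration": rng.uniform(0, 100, 200),
                "heart_rate": rng.uniform(55, 120, 200),
            }
        )
        out = align_activity(act, grid, pd.Timedelta(minutes=15))
        for i, t0 in enumerate(grid):
            m = (act["timestamp"] >= t0) & (act["timestamp"] < t0 + pd.Timedelta(minutes=15))
            if m.any():
                assert out["energy_expenditure"].iloc[i] == pytest.approx(act.loc[m, "energy_expenditure"].sum())
                assert out["acceleration"].iloc[i] == pytest.approx(act.loc[m, "acceleration"].sum())
                assert out["heart_rate"].iloc[i] == pytest.approx(act.loc[m, "heart_rate"].mean())
            else:
                assert not out["activity_avail"].iloc[i]


class TestJoinSleep:
    def sleep(self, rows):
        return pd.DataFrame(
            rows, columns=["subject_id", "sleep_end", "sleep_duration", "deep_sleep_duration"]
        )

    def grid(self, times):
        return pd.DataFrame({"timestamp": [pd.Timestamp(t) for t in times]})

    def test_recent_sleep_joined(self):
        s = self.sleep([("S01", pd.Timestamp("2022-03-02 07:00"), 7.5, 1.5)])
        out = join_sleep(self.grid(["2022-03-02 09:00"]), s)
        assert out.loc[0, "sleep_duration"] == 7.5
        assert out.loc[0, "sleep_avail"]

    def test_sleep_older_than_28h_missing(self):
        s = self.sleep([("S01", pd.Timestamp("2022-03-01 00:00"), 8.0, 2.0)])
        out = join_sleep(self.grid(["2022-03-02 06:00"]), s)  # 30 h later
        assert not out.loc[0, "sleep_avail"]
        assert np.isnan(out.loc[0, "sleep_duration"])

    def test_closest_preceding_wins(self):
        s = self.sleep(
            [("S01", pd.Timestamp("2022-03-01 10:00"), 8.0, 2.0),
             ("S01", pd.Timestamp("2022-03-02 00:00"), 6.0, 1.0)]
        )
        out = join_sleep(self.grid(["2022-03-02 06:00"]), s)  # 20 h and 6 h before
        assert out.loc[0, "sleep_duration"] == 6.0

    def test_boundary_exactly_28h_joined(self):
        s = self.sleep([("S01", pd.Timestamp("2022-03-01 00:00"), 8.0, 2.0)])
        out = join_sleep(self.grid(["2022-03-02 04:00"]), s)
        assert out.loc[0, "sleep_avail"]

    def test_shrinking_window_never_adds_rows(self):
        rng = np.random.default_rng(5)
        s = self.sleep(
            [("S01", EPOCH + pd.Timedelta(hours=float(h)), 7.0, 1.5)
             for h in np.sort(rng.uniform(0, 96, 5))]
        )
        g = self.grid([EPOCH + pd.Timedelta(hours=float(h)) for h in np.sort(rng.uniform(0, 120, 50))])
        wide = join_sleep(g, s, max_hours=28)["sleep_avail"]
        narrow = join_sleep(g, s, max_hours=12)["sleep_avail"]
        assert not (narrow & ~wide).any()


class TestSelectStretches:
    def make(self, ok, subject="S01"):
        df = make_aligned(np.full(len(ok), 5.0), subject=subject)
        df = df.drop(columns="stretch_id")
        df["glucose_avail"] = ok
        return df

    def test_gapfree_subject_retained_whole(self):
        df = self.make(np.ones(14 * 96, dtype=bool))
        aligned, st = select_stretches(df)
        assert len(st) == 1
        assert st.loc[0, "n_rows"] == 14 * 96
        assert aligned["stretch_id"].notna().all()

    def test_short_stretch_dropped(self):
        ok = np.ones(80, dtype=bool)  # 20 h < 24 h
        aligned, st = select_stretches(self.make(ok))
        assert st.empty

    def test_subject_below_total_week_dropped(self):
        # two clean 3-day stretches: each >= 24 h but total 6 d <= 7 d
        ok = np.ones(13 * 96, dtype=bool)
        ok[3 * 96 : 10 * 96] = False
        aligned, st = select_stretches(self.make(ok))
        assert st.empty

    def test_gap_splits_stretch_in_two(self):
        ok = np.ones(14 * 96, dtype=bool)
        ok[5 * 96 : 5 * 96 + 24] = False  # 6-h glucose gap
        aligned, st = select_stretches(self.make(ok))
        assert len(st) == 2

    def test_single_missing_sample_breaks_stretch(self):
        ok = np.ones(15 * 96, dtype=bool)
        ok[7 * 96] = False
        _, st = select_stretches(self.make(ok))
        assert len(st) == 2

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            n = int(rng.integers(200, 2000))
            ok = rng.random(n) > 0.02
            _, st = select_stretches(self.make(ok), min_total_days=0)
            runs = stretches_bruteforce(ok, 96)
            got = [(int(r["n_rows"])) for _, r in st.iterrows()]
            assert got == [b - a for a, b in runs]


class TestSplits:
    def frame(self, days, subject="S01"):
        df = make_aligned(np.full(int(days * 96), 5.0), subject=subject)
        return df

    def test_glucose_split_last_three_days(self):
        out = split_glucose(self.frame(10))
        assert (out["split_glucose"] == "train").sum() == 7 * 96
        assert (out["split_glucose"] == "test").sum() == 3 * 96
        # chronological: all test rows after all train rows
        assert out.loc[out["split_glucose"] == "train", "timestamp"].max() < \
            out.loc[out["split_glucose"] == "test", "timestamp"].min()

    def test_glucose_split_four_days_leaves_one_train_day(self):
        out = split_glucose(self.frame(4))
        assert (out["split_glucose"] == "train").sum() == 96
        assert (out["split_glucose"] == "test").sum() == 3 * 96

    def test_glucose_split_below_four_days_excluded(self):
        with pytest.warns(UserWarning):
            out = split_glucose(self.frame(3.5))
        assert (out["split_glucose"] == "excluded").all()

    def test_meal_split_eleven_days(self):
        out = split_mealdetect(self.frame(11))
        assert (out["split_meal"] == "train").sum() == 4 * 96
        assert (out["split_meal"] == "test").sum() == 3 * 96
        assert (out["split_meal"] == "unused").sum() == 4 * 96

    def test_meal_split_exactly_seven_days(self):
        out = split_mealdetect(self.frame(7))
        assert (out["split_meal"] == "train").sum() == 4 * 96
        assert (out["split_meal"] == "test").sum() == 3 * 96
        assert (out["split_meal"] == "unused").sum() == 0

    def test_meal_split_below_seven_days_excluded(self):
        with pytest.warns(UserWarning):
            out = split_mealdetect(self.frame(6))
        assert (out["split_meal"] == "excluded").all()

    def test_partition_property(self, small_aligned):
        aligned, _, _ = small_aligned
        for splitter, col in ((split_glucose, "split_glucose"), (split_mealdetect, "split_meal")):
            out = splitter(aligned)
            tr = out.loc[out[col] == "train", ["subject_id", "timestamp"]]
            te = out.loc[out[col] == "test", ["subject_id", "timestamp"]]
            merged = tr.merge(te, on=["subject_id", "timestamp"])
            assert merged.empty


def test_align_cohort_meal_calories_land_on_grid(small_cohort):
    cfg, cohort = small_cohort
    meals = aggregate_meals(cohort.diary)
    aligned = preprocess.align_cohort(cohort.glucose, meals, cohort.activity, cohort.sleep)
    # total calories are conserved by the grid mapping
    assert aligned["kcal_total"].sum() == pytest.approx(meals["kcal_total"].sum())
    # glucose present on every grid row for a gap-free cohort
    assert aligned["glucose_avail"].all()
    assert aligned.groupby("subject_id")["timestamp"].apply(
        lambda s: (s.diff().dropna() == pd.Timedelta(minutes=15)).all()
    ).all()
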