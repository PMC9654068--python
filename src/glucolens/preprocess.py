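"""Multimodal aggregation onto the CGM grid and data-eligibility selection.

Steps, in pipeline order:

1. diary items eaten within 15 min of the previous item are chained into a
   single meal event with Atwater calories (4/9/4 kcal per g of
   carbohydrate/fat/protein) and calorie fractions;
2. activity samples are aggregated per 15-min CGM interval (energy
   expenditure and acceleration summed, heart rate averaged);
3. each grid row is joined with the closest preceding sleep record that
   ended no more than 28 h earlier;
4. uninterrupted stretches — maximal runs where both glucose and activity
   are present on every grid interval — are selected; stretches shorter
   than 24 h are dropped and subjects whose stretches total <= 7 days are
   excluded;
5. rows are partitioned into train/test for the two analyses: glucose
   prediction holds out the last 3 days of available data, meal detection
   trains on the first 4 days and tests on the following 3.

All grids are half-open ``[t, t + step)`` with timestamps treated as UTC.
The food diary has no sampling cadence of its own, so it is treated as
available whenever the devices were worn; only glucose and activity breaks
interrupt a stretch.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ATWATER",
    "aggregate_meals",
    "align_activity",
    "join_sleep",
    "align_cohort",
    "select_stretches",
    "split_glucose",
    "split_mealdetect",
    "EligibilityError",
]

#: kcal per gram of carbohydrate / fat / protein
ATWATER = {"carb": 4.0, "fat": 9.0, "protein": 4.0}

MEAL_CHAIN_MIN = 15.0  # diary items within this many minutes form one meal
SLEEP_MAX_HOURS = 28.0

MEAL_COLS = [
    "kcal_total",
    "kcal_carb",
    "kcal_fat",
    "kcal_protein",
    "frac_carb",
    "frac_fat",
    "frac_protein",
]


class EligibilityError(RuntimeError):
    """No subject satisfies the data-eligibility rules."""


def aggregate_meals(diary: pd.DataFrame) -> pd.DataFrame:
    """Chain diary items eaten within 15 min into single meal events.

    Chaining is transitive: each item merges with the previous one when their
    timestamps are <= 15 min apart, so a long multi-item meal forms one event
    stamped at its first item's time.  Calories come from Atwater factors and
    the calorie fractions from carbohydrate/fat/protein are derived (0 when
    the event carries no calories).
    """
    for col in ("carb_g", "fat_g", "protein_g"):
        if (diary[col] < 0).any():
            raise ValueError(f"negative grams in diary column {col}")
    if diary.empty:
        return pd.DataFrame(columns=["subject_id", "timestamp"] + MEAL_COLS)
    d = diary.sort_values(["subject_id", "timestamp"], kind="stable").reset_index(drop=True)
    gap = d.groupby("subject_id")["timestamp"].diff()
    new_event = gap.isna() | (gap > pd.Timedelta(minutes=MEAL_CHAIN_MIN))
    event_id = new_event.cumsum()
    out = (
        d.assign(_eid=event_id)
        .groupby("_eid", sort=True)
        .agg(
            subject_id=("subject_id", "first"),
            timestamp=("timestamp", "first"),
            carb_g=("carb_g", "sum"),
            fat_g=("fat_g", "sum"),
            protein_g=("protein_g", "sum"),
        )
        .reset_index(drop=True)
    )
    out["kcal_carb"] = ATWATER["carb"] * out.pop("carb_g")
    out["kcal_fat"] = ATWATER["fat"] * out.pop("fat_g")
    out["kcal_protein"] = ATWATER["protein"] * out.pop("protein_g")
    out["kcal_total"] = out["kcal_carb"] + out["kcal_fat"] + out["kcal_protein"]
    total = out["kcal_total"].to_numpy()
    safe = np.where(total > 0, total, 1.0)
    for macro in ("carb", "fat", "protein"):
        out[f"frac_{macro}"] = np.where(total > 0, out[f"kcal_{macro}"] / safe, 0.0)
    return out[["subject_id", "timestamp"] + MEAL_COLS]


def align_activity(activity: pd.DataFrame, grid: pd.DatetimeIndex, step: pd.Timedelta) -> pd.DataFrame:
    """Aggregate activity samples of one subject onto the CGM grid.

    Per interval ``[t, t + step)``: energy expenditure and acceleration are
    summed (extensive), heart rate is averaged (intensive).  Intervals with no
    sample are flagged unavailable.
    """
    out = pd.DataFrame(
        index=grid,
        data={
            "energy_expenditure": 0.0,
            "acceleration": 0.0,
            "heart_rate": np.nan,
            "activity_avail": False,
        },
    )
    if activity.empty:
        return out
    binned = activity["timestamp"].dt.floor(step)
    agg = activity.groupby(binned).agg(
        energy_expenditure=("energy_expenditure", "sum"),
        acceleration=("acceleration", "sum"),
        heart_rate=("heart_rate", "mean"),
        n=("timestamp", "size"),
    )
    agg = agg.reindex(grid)
    avail = agg["n"].fillna(0).to_numpy() > 0
    out["energy_expenditure"] = agg["energy_expenditure"].fillna(0.0).to_numpy()
    out["acceleration"] = agg["acceleration"].fillna(0.0).to_numpy()
    out["heart_rate"] = agg["heart_rate"].to_numpy()
    out["activity_avail"] = avail
    return out


def join_sleep(
    grid_df: pd.DataFrame, sleep: pd.DataFrame, max_hours: float = SLEEP_MAX_HOURS
) -> pd.DataFrame:
    """Attach to each grid row the closest preceding sleep record.

    A record qualifies when its ``sleep_end`` is at or before the row time and
    no more than ``max_hours`` earlier; rows with no qualifying record get
    missing sleep columns and ``sleep_avail=False``.  ``grid_df`` must carry a
    ``timestamp`` column and a single subject.
    """
    s = sleep.sort_values("sleep_end")[["sleep_end", "sleep_duration", "deep_sleep_duration"]]
    joined = pd.merge_asof(
        grid_df.sort_values("timestamp"),
        s,
        left_on="timestamp",
        right_on="sleep_end",
        direction="backward",
        tolerance=pd.Timedelta(hours=max_hours),
    )
    joined["sleep_avail"] = joined["sleep_end"].notna()
    return joined.drop(columns=["sleep_end"])


def align_cohort(
    glucose: pd.DataFrame,
    meals: pd.DataFrame,
    activity: pd.DataFrame,
    sleep: pd.DataFrame,
    grid_step_min: int = 15,
) -> pd.DataFrame:
    """Build the per-subject 15-min multimodal grid (the aligned frame).

    For each subject the grid spans from the first to the last glucose
    timestamp.  Glucose values land on their grid rows; activity is
    aggregated per interval; meal events contribute their calories and
    fractions to the interval containing the meal start (0 when no meal);
    sleep is joined backward within 28 h.  Availability flags mark, per
    modality, whether the interval has data.
    """
    step = pd.Timedelta(minutes=grid_step_min)
    frames = []
    for subj, g in glucose.groupby("subject_id", sort=True):
        g = g.sort_values("timestamp")
        grid = pd.date_range(g["timestamp"].min().floor(step), g["timestamp"].max().floor(step), freq=step)
        df = pd.DataFrame({"timestamp": grid})
        glu = g.set_index(g["timestamp"].dt.floor(step))["glucose"]
        glu = glu[~glu.index.duplicated(keep="first")].reindex(grid)
        df["glucose"] = glu.to_numpy()
        df["glucose_avail"] = ~np.isnan(df["glucose"].to_numpy())

        act = align_activity(activity[activity["subject_id"] == subj], grid, step)
        for col in act.columns:
            df[col] = act[col].to_numpy()

        m = meals[meals["subject_id"] == subj]
        for col in MEAL_COLS:
            df[col] = 0.0
        df["has_meal"] = False
        if not m.empty:
            binned = m["timestamp"].dt.floor(step)
            kcal = m.groupby(binned)[["kcal_total", "kcal_carb", "kcal_fat", "kcal_protein"]].sum()
            kcal = kcal[kcal.index.isin(grid)]
            pos = pd.Index(grid).get_indexer(kcal.index)
            for col in ("kcal_total", "kcal_carb", "kcal_fat", "kcal_protein"):
                arr = df[col].to_numpy()
                arr[pos] = kcal[col].to_numpy()
                df[col] = arr
            total = df["kcal_total"].to_numpy()
            safe = np.where(total > 0, total, 1.0)
            for macro in ("carb", "fat", "protein"):
                df[f"frac_{macro}"] = np.where(total > 0, df[f"kcal_{macro}"] / safe, 0.0)
            df["has_meal"] = total > 0

        df = join_sleep(df, sleep[sleep["subject_id"] == subj])
        df.insert(0, "subject_id", subj)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def select_stretches(
    aligned: pd.DataFrame,
    grid_step_min: int = 15,
    min_stretch_hours: float = 24.0,
    min_total_days: float = 7.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark uninterrupted multimodal stretches and apply eligibility rules.

    A stretch is a maximal run of consecutive grid rows where both the
    glucose and the activity flags are continuously present (a single missing
    interval breaks it).  Stretches shorter than ``min_stretch_hours`` are
    dropped; subjects whose retained stretches do not total more than
    ``min_total_days`` are excluded entirely.

    Returns the aligned frame with a nullable ``stretch_id`` column (rows
    outside any retained stretch get NA) and a stretch table with one row per
    retained stretch (``subject_id, stretch_id, start, end, n_rows``; ``end``
    is exclusive).
    """
    step = pd.Timedelta(minutes=grid_step_min)
    min_rows = int(round(min_stretch_hours * 60 / grid_step_min))
    total_rows_needed = min_total_days * 24 * 60 / grid_step_min
    aligned = aligned.copy()
    aligned["stretch_id"] = pd.array([pd.NA] * len(aligned), dtype="Int64")
    records = []
    next_id = 0
    for subj, sub in aligned.groupby("subject_id", sort=True):
        ok = (sub["glucose_avail"] & sub["activity_avail"]).to_numpy()
        idx = sub.index.to_numpy()
        # run-length encode the availability mask
        bounds = np.flatnonzero(np.diff(np.concatenate([[0], ok.astype(int), [0]])))
        runs = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
        kept = [(a, b) for a, b in runs if b - a >= min_rows]
        total = sum(b - a for a, b in kept)
        if total <= total_rows_needed:
            continue
        for a, b in kept:
            rows = idx[a:b]
            aligned.loc[rows, "stretch_id"] = next_id
            records.append(
                {
                    "subject_id": subj,
                    "stretch_id": next_id,
                    "start": sub["timestamp"].iloc[a],
                    "end": sub["timestamp"].iloc[b - 1] + step,
                    "n_rows": int(b - a),
                }
            )
            next_id += 1
    stretch_table = pd.DataFrame(
        records, columns=["subject_id", "stretch_id", "start", "end", "n_rows"]
    )
    return aligned, stretch_table


def split_glucose(
    aligned: pd.DataFrame, grid_step_min: int = 15, test_days: float = 3.0, min_days: float = 4.0
) -> pd.DataFrame:
    """Partition stretch rows for glucose prediction: last 3 days held out.

    Per subject, rows in the final ``test_days`` of *available* data (measured
    back from the end of the subject's last stretch) form the test set; all
    earlier stretch rows form the training set.  Subjects with less than
    ``min_days`` of available data are excluded with a warning (their
    training set would be empty).  Adds a ``split_glucose`` column with
    values train/test/excluded (rows outside stretches are excluded).
    """
    aligned = aligned.copy()
    aligned["split_glucose"] = "excluded"
    step_h = grid_step_min / 60.0
    for subj, sub in aligned.groupby("subject_id", sort=True):
        in_stretch = sub["stretch_id"].notna()
        if not in_stretch.any():
            continue
        avail_h = in_stretch.sum() * step_h
        if avail_h < min_days * 24.0:
            warnings.warn(f"subject {subj}: <{min_days} days available, excluded from glucose split")
            continue
        t_end = sub.loc[in_stretch, "timestamp"].max() + pd.Timedelta(minutes=grid_step_min)
        cutoff = t_end - pd.Timedelta(days=test_days)
        rows = sub.index[in_stretch]
        is_test = sub.loc[rows, "timestamp"] >= cutoff
        aligned.loc[rows[is_test.to_numpy()], "split_glucose"] = "test"
        aligned.loc[rows[~is_test.to_numpy()], "split_glucose"] = "train"
    return aligned


def split_mealdetect(
    aligned: pd.DataFrame,
    grid_step_min: int = 15,
    train_days: float = 4.0,
    test_days: float = 3.0,
) -> pd.DataFrame:
    """Partition stretch rows for meal detection: first 4 days train, next 3 test.

    Both windows are measured forward from the start of each subject's first
    stretch; data after day 7 stay unused (the training window is kept small
    on purpose — diary keeping is burdensome in practice).  Subjects with less
    than 7 days of available data are excluded with a warning.  Adds a
    ``split_meal`` column with values train/test/unused/excluded.
    """
    aligned = aligned.copy()
    aligned["split_meal"] = "excluded"
    step_h = grid_step_min / 60.0
    for subj, sub in aligned.groupby("subject_id", sort=True):
        in_stretch = sub["stretch_id"].notna()
        if not in_stretch.any():
            continue
        avail_h = in_stretch.sum() * step_h
        if avail_h < (train_days + test_days) * 24.0:
            warnings.warn(
                f"subject {subj}: <{train_days + test_days} days available, excluded from meal split"
            )
            continue
        t0 = sub.loc[in_stretch, "timestamp"].min()
        rows = sub.index[in_stretch]
        ts = sub.loc[rows, "timestamp"]
        train_end = t0 + pd.Timedelta(days=train_days)
        test_end = train_end + pd.Timedelta(days=test_days)
        lab = np.where(ts < train_end, "train", np.where(ts < test_end, "test", "unused"))
        aligned.loc[rows, "split_meal"] = lab
    return aligned
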