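import numpy as np
import pandas as pd
import pytest

from glucolens import preprocess, synthetic

EPOCH = synthetic.EPOCH


def make_aligned(glucose: np.ndarray, *, subject="S01", stretch=0, start=None, step_min=15,
                 has_meal=None, **extra) -> pd.DataFrame:
    """Minimal aligned-frame fragment for feature-level tests."""
    n = len(glucose)
    start = EPOCH if start is None else start
    df = pd.DataFrame(
        {
            "subject_id": subject,
            "timestamp": start + pd.to_timedelta(np.arange(n) * step_min, unit="m"),
            "glucose": np.asarray(glucose, dtype=float),
            "glucose_avail": True,
            "energy_expenditure": 0.0,
            "acceleration": 0.0,
            "heart_rate": 60.0,
            "activity_avail": True,
            "kcal_total": 0.0,
            "kcal_carb": 0.0,
            "kcal_fat": 0.0,
            "kcal_protein": 0.0,
            "frac_carb": 0.0,
            "frac_fat": 0.0,
            "frac_protein": 0.0,
            "has_meal": False,
            "sleep_duration": 7.0,
            "deep_sleep_duration": 1.5,
            "sleep_avail": True,
        }
    )
    df["stretch_id"] = pd.array([stretch] * n, dtype="Int64")
    if has_meal is not None:
        df["has_meal"] = has_meal
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthetic.CohortConfig(n_subjects=3, n_days=9, seed=11)
    return cfg, synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_aligned(small_cohort):
    cfg, cohort = small_cohort
    meals = preprocess.aggregate_meals(cohort.diary)
    aligned = preprocess.align_cohort(cohort.glucose, meals, cohort.activity, cohort.sleep)
    aligned, stretches = preprocess.select_stretches(aligned)
    return aligned, stretches, meals
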