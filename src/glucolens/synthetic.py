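"""Synthetic free-living wearable cohort generator.

Emulates a two-week self-monitoring study in healthy adults: interstitial
glucose sampled every 15 minutes by a CGM sensor, a timestamped food diary
with macronutrient grams, wrist-worn activity tracking (energy expenditure,
acceleration counts, heart rate), and nightly sleep records.  Each subject's
glucose trace is composed from a personal baseline, meal-driven excursions,
an activity-driven depression, a prior-night-sleep shift, and AR(1) sensor
noise.  The generative parameters of every subject are returned as ground
truth so downstream detection and prediction stages can be validated against
a known signal.

The glucose excursion after a meal follows a gamma-like impulse response

    dg(t) = A * u * exp(1 - u),   u = t / tau,  t >= 0

with amplitude ``A = s_i * carb_kcal / 100`` (mmol/L), which peaks at
``t = tau`` with value ``A`` and decays smoothly to zero.  Activity lowers
glucose proportionally to the energy expended in the previous hour; short
prior-night sleep raises next-day glucose.  Device failures are emulated by
removing contiguous blocks of rows per modality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GapSpec",
    "CohortConfig",
    "SubjectTruth",
    "RawCohort",
    "glucose_kernel",
    "simulate_cohort",
    "inject_gaps",
    "simulate",
    "write_cohort",
    "read_cohort",
    "default_gap_spec",
]

#: start of the simulated study period (interpreted as UTC)
EPOCH = pd.Timestamp("2022-03-01 00:00:00")

MINUTES_PER_DAY = 24 * 60


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class GapSpec:
    """Per-modality device-failure model: each day a contiguous gap occurs
    with probability ``prob_per_day``; its length is uniform between
    ``min_hours`` and ``max_hours``."""

    prob_per_day: float = 0.0
    min_hours: float = 2.0
    max_hours: float = 8.0


def default_gap_spec() -> dict[str, GapSpec]:
    """Mild gap rates: most subjects keep >7 days of joint coverage."""
    return {
        "glucose": GapSpec(0.04, 2.0, 8.0),
        "activity": GapSpec(0.06, 2.0, 8.0),
        "diary": GapSpec(0.0),
        "sleep": GapSpec(0.03, 24.0, 24.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and generative parameters of a synthetic cohort.

    Defaults mirror the emulated study: 24 subjects, 14 days, 15-min CGM
    cadence, 3-5 meals/day, and normoglycemic traces around 5 mmol/L.
    """

    n_subjects: int = 24
    n_days: int = 14
    grid_step_min: int = 15
    meals_per_day: tuple[int, int] = (3, 5)
    carb_grams: tuple[float, float] = (20.0, 100.0)
    fat_grams: tuple[float, float] = (5.0, 40.0)
    protein_grams: tuple[float, float] = (5.0, 40.0)
    baseline_glucose_mean: float = 5.0
    baseline_glucose_sd: float = 0.3
    carb_sensitivity_mean: float = 1.0
    carb_sensitivity_sd: float = 0.15
    kernel_tau_min: float = 45.0
    activity_beta: float = 0.002  # mmol/L depression per kcal in prior hour
    sleep_gamma: float = 0.05  # mmol/L per hour of sleep below 7 h
    noise_sd: float = 0.15  # stationary AR(1) sd, mmol/L
    noise_ar1: float = 0.5
    gap_spec: dict[str, GapSpec] = field(default_factory=default_gap_spec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.grid_step_min <= 0 or MINUTES_PER_DAY % self.grid_step_min:
            raise ConfigError("grid_step_min must be positive and divide 24 h")
        for name in ("baseline_glucose_sd", "carb_sensitivity_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.noise_ar1 < 1.0):
            raise ConfigError("noise_ar1 must lie in [0, 1)")
        if self.kernel_tau_min <= 0:
            raise ConfigError("kernel_tau_min must be > 0")
        lo, hi = self.meals_per_day
        if lo < 0 or hi < lo:
            raise ConfigError("meals_per_day range must satisfy 0 <= lo <= hi")
        for name in ("carb_grams", "fat_grams", "protein_grams"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigError(f"{name} range must satisfy 0 <= lo <= hi")
        for mod, spec in self.gap_spec.items():
            if not (0.0 <= spec.prob_per_day <= 1.0):
                raise ConfigError(f"gap probability for {mod} must be in [0, 1]")

    @property
    def steps_per_day(self) -> int:
        return MINUTES_PER_DAY // self.grid_step_min

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["gap_spec"] = {k: dataclasses.asdict(v) for k, v in self.gap_spec.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "gap_spec" in d:
            d["gap_spec"] = {k: GapSpec(**v) for k, v in d["gap_spec"].items()}
        for key in ("meals_per_day", "carb_grams", "fat_grams", "protein_grams"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SubjectTruth:
    """Generative ground truth for one subject, for recovery tests."""

    subject_id: str
    baseline: float  # b_i, mmol/L
    carb_sensitivity: float  # s_i, dimensionless
    activity_beta: float  # mmol/L per kcal
    sleep_gamma: float  # mmol/L per h
    kernel_tau_min: float  # min


@dataclass
class RawCohort:
    """The four simulated data streams plus per-subject ground truth.

    ``glucose``: subject_id, timestamp, glucose (mmol/L)
    ``diary``: subject_id, timestamp, carb_g, fat_g, protein_g
    ``activity``: subject_id, timestamp, energy_expenditure (kcal/sample),
                  acceleration (counts), heart_rate (bpm)
    ``sleep``: subject_id, sleep_end, sleep_duration (h), deep_sleep_duration (h)
    """

    glucose: pd.DataFrame
    diary: pd.DataFrame
    activity: pd.DataFrame
    sleep: pd.DataFrame
    truth: list[SubjectTruth]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.truth])


def glucose_kernel(
    t_since_meal_min: np.ndarray | float,
    carb_kcal: float,
    carb_sensitivity: float,
    tau_min: float,
) -> np.ndarray | float:
    """Incremental glucose (mmol/L) at ``t`` minutes after a meal.

    ``dg = A * u * exp(1 - u)`` with ``u = t/tau`` for ``t >= 0`` (0 before the
    meal) and amplitude ``A = carb_sensitivity * carb_kcal / 100``.  The
    response peaks at ``t = tau`` with value ``A``.
    """
    if tau_min <= 0:
        raise ValueError("tau_min must be > 0")
    if carb_kcal < 0:
        raise ValueError("carb_kcal must be >= 0")
    if carb_sensitivity < 0:
        raise ValueError("carb_sensitivity must be >= 0")
    t = np.asarray(t_since_meal_min, dtype=float)
    amp = carb_sensitivity * carb_kcal / 100.0
    u = np.where(t > 0, t / tau_min, 0.0)
    out = amp * u * np.exp(1.0 - u)
    out = np.where(t >= 0, out, 0.0)
    if np.isscalar(t_since_meal_min):
        return float(out)
    return out


# main mealtimes (hours of day); extra snacks fill in between
_MAIN_MEAL_HOURS = (7.5, 12.5, 18.5)
_SNACK_HOURS = (10.5, 15.5)
_MEAL_JITTER_SD_MIN = 30.0
_ACTIVITY_STEP_MIN = 5  # wristband sampling, finer than the CGM grid


def _simulate_subject(
    cfg: CohortConfig, subject_id: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SubjectTruth]:
    step = pd.Timedelta(minutes=cfg.grid_step_min)
    n_rows = cfg.n_days * cfg.steps_per_day
    grid = pd.DatetimeIndex(EPOCH + step * np.arange(n_rows))
    grid_min = ((grid - EPOCH) / pd.Timedelta(minutes=1)).to_numpy()  # float minutes

    # --- subject-level generative parameters
    b = max(3.0, rng.normal(cfg.baseline_glucose_mean, cfg.baseline_glucose_sd))
    s = max(0.0, rng.normal(cfg.carb_sensitivity_mean, cfg.carb_sensitivity_sd))
    tau = float(np.clip(rng.normal(cfg.kernel_tau_min, 5.0), 15.0, None))
    beta = cfg.activity_beta * rng.uniform(0.8, 1.2)
    gamma = cfg.sleep_gamma * rng.uniform(0.8, 1.2)
    truth = SubjectTruth(subject_id, b, s, beta, gamma, tau)

    # --- nightly sleep records (sleep_end around 07:00 each morning)
    sleep_rows = []
    for day in range(cfg.n_days):
        end_min = round(day * MINUTES_PER_DAY + 7 * 60 + rng.normal(0.0, 45.0))
        dur = float(np.clip(rng.normal(7.2, 0.8), 4.0, 10.0))
        deep = rng.uniform(0.15, 0.25) * dur
        sleep_rows.append((subject_id, EPOCH + pd.Timedelta(minutes=end_min), dur, deep))
    sleep = pd.DataFrame(
        sleep_rows, columns=["subject_id", "sleep_end", "sleep_duration", "deep_sleep_duration"]
    ).sort_values("sleep_end", ignore_index=True)

    # --- meals: jittered mains plus snacks; diary items occasionally split
    lo, hi = cfg.meals_per_day
    meal_times_min: list[float] = []
    meal_grams: list[tuple[float, float, float]] = []
    diary_rows = []
    for day in range(cfg.n_days):
        n_meals = int(rng.integers(lo, hi + 1))
        hours = list(_MAIN_MEAL_HOURS[: min(n_meals, 3)])
        hours += list(_SNACK_HOURS[: max(0, n_meals - 3)])
        for h in hours:
            t_min = day * MINUTES_PER_DAY + h * 60 + rng.normal(0.0, _MEAL_JITTER_SD_MIN)
            t_min = float(np.clip(t_min, day * MINUTES_PER_DAY, (day + 1) * MINUTES_PER_DAY - 1))
            carb = rng.uniform(*cfg.carb_grams)
            fat = rng.uniform(*cfg.fat_grams)
            prot = rng.uniform(*cfg.protein_grams)
            meal_times_min.append(t_min)
            meal_grams.append((carb, fat, prot))
            ts = EPOCH + pd.Timedelta(minutes=round(t_min))
            # a third of meals are logged as two diary items a few minutes apart
            if rng.random() < 0.3:
                frac = rng.uniform(0.3, 0.7)
                delta = pd.Timedelta(minutes=round(rng.uniform(3.0, 12.0)))
                diary_rows.append((subject_id, ts, carb * frac, fat * frac, prot * frac))
                diary_rows.append(
                    (subject_id, ts + delta, carb * (1 - frac), fat * (1 - frac), prot * (1 - frac))
                )
            else:
                diary_rows.append((subject_id, ts, carb, fat, prot))
    diary = pd.DataFrame(
        diary_rows, columns=["subject_id", "timestamp", "carb_g", "fat_g", "protein_g"]
    ).sort_values("timestamp", kind="stable", ignore_index=True)

    # --- wristband activity at 5-min sampling with 0-2 exercise bouts/day
    n_act = cfg.n_days * MINUTES_PER_DAY // _ACTIVITY_STEP_MIN
    act_times_min = np.arange(n_act, dtype=float) * _ACTIVITY_STEP_MIN
    ee = np.maximum(0.0, rng.normal(6.5, 0.8, n_act))  # resting kcal per 5 min
    acn = np.maximum(0.0, rng.normal(50.0, 20.0, n_act))
    for day in range(cfg.n_days):
        for _ in range(int(rng.integers(0, 3))):
            start = day * MINUTES_PER_DAY + rng.uniform(8.0, 20.0) * 60
            dur = rng.uniform(30.0, 60.0)
            in_bout = (act_times_min >= start) & (act_times_min < start + dur)
            ee[in_bout] += rng.uniform(20.0, 40.0)
            acn[in_bout] += np.maximum(0.0, rng.normal(3000.0, 300.0, int(in_bout.sum())))
    hr = 60.0 + 0.02 * acn + rng.normal(0.0, 3.0, n_act)
    activity = pd.DataFrame(
        {
            "subject_id": subject_id,
            "timestamp": EPOCH + pd.to_timedelta(act_times_min, unit="m"),
            "energy_expenditure": ee,
            "acceleration": acn,
            "heart_rate": hr,
        }
    )

    # --- glucose composition on the CGM grid
    g = np.full(n_rows, b)
    # prior-night sleep shift (7 h is the neutral duration)
    ends_min = (sleep["sleep_end"] - EPOCH) / pd.Timedelta(minutes=1)
    idx = np.searchsorted(ends_min.to_numpy(), grid_min, side="right") - 1
    prev_dur = np.where(idx >= 0, sleep["sleep_duration"].to_numpy()[np.maximum(idx, 0)], 7.0)
    within = np.where(idx >= 0, grid_min - ends_min.to_numpy()[np.maximum(idx, 0)] <= 28 * 60, False)
    prev_dur = np.where(within, prev_dur, 7.0)
    g = g + gamma * (7.0 - prev_dur)
    # meal excursions
    for t_m, (carb, _, _) in zip(meal_times_min, meal_grams):
        g = g + glucose_kernel(grid_min - t_m, 4.0 * carb, s, tau)
    # activity depression: energy expended in the preceding hour
    order = np.searchsorted(act_times_min, grid_min, side="right")
    cum = np.concatenate([[0.0], np.cumsum(ee)])
    order_lo = np.searchsorted(act_times_min, grid_min - 60.0, side="right")
    ee_prev_hour = cum[order] - cum[order_lo]
    g = g - beta * ee_prev_hour
    # AR(1) sensor noise with stationary sd noise_sd
    eps = np.zeros(n_rows)
    rho = cfg.noise_ar1
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - rho**2)
    draws = rng.normal(0.0, 1.0, n_rows)
    eps[0] = cfg.noise_sd * draws[0]
    for t in range(1, n_rows):
        eps[t] = rho * eps[t - 1] + innov_sd * draws[t]
    g = np.maximum(g + eps, 0.1)

    glucose = pd.DataFrame({"subject_id": subject_id, "timestamp": grid, "glucose": g})
    return glucose, diary, activity, sleep, truth


def simulate_cohort(config: CohortConfig) -> RawCohort:
    """Simulate a gap-free multimodal cohort; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    parts: list[tuple] = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        parts.append(_simulate_subject(config, subject_id, rng))
    glucose = pd.concat([p[0] for p in parts], ignore_index=True)
    diary = pd.concat([p[1] for p in parts], ignore_index=True)
    activity = pd.concat([p[2] for p in parts], ignore_index=True)
    sleep = pd.concat([p[3] for p in parts], ignore_index=True)
    truth = [p[4] for p in parts]
    return RawCohort(glucose, diary, activity, sleep, truth)


_TIME_COLS = {"glucose": "timestamp", "diary": "timestamp", "activity": "timestamp", "sleep": "sleep_end"}


def inject_gaps(
    cohort: RawCohort, gap_spec: dict[str, GapSpec] | None = None, seed: int = 0
) -> RawCohort:
    """Remove contiguous per-modality blocks of rows to emulate device failures.

    For each subject, day and modality, a gap starts at a uniform time of day
    with the modality's daily probability and removes all rows within the gap
    window.  Ground truth is unchanged; deterministic given the seed.
    """
    if gap_spec is None:
        gap_spec = default_gap_spec()
    for mod, spec in gap_spec.items():
        if not (0.0 <= spec.prob_per_day <= 1.0):
            raise ConfigError(f"gap probability for {mod} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tables = {
        "glucose": cohort.glucose,
        "diary": cohort.diary,
        "activity": cohort.activity,
        "sleep": cohort.sleep,
    }
    subjects = sorted(cohort.glucose["subject_id"].unique())
    n_days = int(
        np.ceil(
            (cohort.glucose["timestamp"].max() - EPOCH) / pd.Timedelta(days=1)
        )
    )
    out: dict[str, pd.DataFrame] = {}
    masks = {mod: np.ones(len(df), dtype=bool) for mod, df in tables.items()}
    for subj in subjects:
        for mod in ("glucose", "diary", "activity", "sleep"):
            spec = gap_spec.get(mod, GapSpec())
            df = tables[mod]
            tcol = _TIME_COLS[mod]
            for day in range(n_days):
                if rng.random() >= spec.prob_per_day:
                    continue
                start_min = day * MINUTES_PER_DAY + rng.uniform(0, MINUTES_PER_DAY)
                length_min = rng.uniform(spec.min_hours, spec.max_hours) * 60
                t0 = EPOCH + pd.Timedelta(minutes=start_min)
                t1 = t0 + pd.Timedelta(minutes=length_min)
                hit = (
                    (df["subject_id"] == subj) & (df[tcol] >= t0) & (df[tcol] < t1)
                ).to_numpy()
                masks[mod] &= ~hit
    for mod, df in tables.items():
        out[mod] = df.loc[masks[mod]].reset_index(drop=True)
    return RawCohort(out["glucose"], out["diary"], out["activity"], out["sleep"], cohort.truth)


def simulate(config: CohortConfig) -> RawCohort:
    """Simulate a cohort and apply the configured device-gap model."""
    cohort = simulate_cohort(config)
    return inject_gaps(cohort, config.gap_spec, seed=config.seed + 1)


def write_cohort(cohort: RawCohort, outdir: str | Path, parquet: bool = False) -> None:
    """Write the four tables (+ truth) as RFC-4180 CSV, optionally Parquet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "glucose": cohort.glucose,
        "diary": cohort.diary,
        "activity": cohort.activity,
        "sleep": cohort.sleep,
        "truth": cohort.truth_frame(),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, date_format="%Y-%m-%dT%H:%M:%SZ")
        if parquet:
            df.to_parquet(outdir / f"{name}.parquet")


def read_cohort(indir: str | Path) -> RawCohort:
    """Read a cohort previously written by :func:`write_cohort` (CSV)."""
    indir = Path(indir)
    glucose = pd.read_csv(indir / "glucose.csv", parse_dates=["timestamp"])
    diary = pd.read_csv(indir / "diary.csv", parse_dates=["timestamp"])
    activity = pd.read_csv(indir / "activity.csv", parse_dates=["timestamp"])
    sleep = pd.read_csv(indir / "sleep.csv", parse_dates=["sleep_end"])
    for df, col in ((glucose, "timestamp"), (diary, "timestamp"), (activity, "timestamp"), (sleep, "sleep_end")):
        df[col] = pd.to_datetime(df[col]).dt.tz_localize(None)
    truth = []
    truth_path = indir / "truth.csv"
    if truth_path.exists():
        for rec in pd.read_csv(truth_path).to_dict("records"):
            truth.append(SubjectTruth(**rec))
    return RawCohort(glucose, diary, activity, sleep, truth)
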