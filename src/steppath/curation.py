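"""Cohort construction from raw device and EHR records.

Three stages, mirroring the curation rules for wearable step streams:
day-level validity filters (wear time, step bounds, adult age), monthly
exposure aggregation with a minimum-valid-days rule, and assembly of the
analytic cohort with eligibility (non-obese at baseline) and a 6-month
incident-obesity landmark.  Every exclusion is counted in an attrition
table so that input persons = analytic persons + sum of per-rule removals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


@dataclass
class CurationConfig:
    min_wear_minutes: float = 600.0     # 10 hours
    min_steps: int = 100                # inclusive lower bound
    max_steps: int = 45000              # inclusive upper bound
    min_valid_days: int = 15            # per calendar month
    min_age: float = 18.0
    landmark_years: float = 0.5         # events earlier than this exclude the person
    baseline_window_days: float = 180.0  # BMI search window around monitoring start
    obesity_bmi: float = 30.0

    def validate(self) -> None:
        if self.min_wear_minutes < 0 or self.min_valid_days < 1:
            raise ValueError("curation thresholds must be positive")
        if self.min_steps > self.max_steps:
            raise ValueError("min_steps exceeds max_steps")


def filter_valid_days(
    records: pd.DataFrame,
    ages: pd.Series | dict | None = None,
    config: CurationConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Keep days with >= 10 h wear, steps in [100, 45000], and age >= 18.

    Bounds are inclusive: a day at exactly 100 or 45000 steps survives.
    ``ages`` optionally maps person_id to age (years) at that person's first
    record; age on later days accrues with calendar time.  Days with missing
    wear time are removed and counted in the audit, not raised.

    Returns the retained records (order preserved) and an audit dict with
    per-rule removal counts.  Idempotent: re-filtering the output is a no-op.
    """
    config = config or CurationConfig()
    config.validate()
    if records.empty:
        return records.copy(), {
            "input_days": 0, "missing_wear": 0, "low_wear": 0,
            "low_steps": 0, "high_steps": 0, "under_age": 0, "valid_days": 0,
        }
    rec = records.copy()
    wear = pd.to_numeric(rec["wear_minutes"], errors="coerce")
    missing_wear = wear.isna()
    low_wear = ~missing_wear & (wear < config.min_wear_minutes)
    low_steps = rec["steps"] < config.min_steps
    high_steps = rec["steps"] > config.max_steps

    under_age = pd.Series(False, index=rec.index)
    if ages is not None:
        ages = pd.Series(ages)
        dates = pd.to_datetime(rec["date"])
        first = dates.groupby(rec["person_id"]).transform("min")
        elapsed = (dates - first).dt.days / DAYS_PER_YEAR
        age_at_day = rec["person_id"].map(ages) + elapsed
        under_age = age_at_day.notna() & (age_at_day < config.min_age)

    bad = missing_wear | low_wear | low_steps | high_steps | under_age
    audit = {
        "input_days": int(len(rec)),
        "missing_wear": int(missing_wear.sum()),
        "low_wear": int(low_wear.sum()),
        "low_steps": int((low_steps & ~missing_wear & ~low_wear).sum()),
        "high_steps": int((high_steps & ~missing_wear & ~low_wear).sum()),
        "under_age": int((under_age & ~(missing_wear | low_wear | low_steps | high_steps)).sum()),
        "valid_days": int((~bad).sum()),
    }
    return rec.loc[~bad].copy(), audit


def monthly_means(
    valid_days: pd.DataFrame, config: CurationConfig | None = None
) -> pd.DataFrame:
    """Per-person calendar-month mean daily steps, the time-varying exposure.

    Months with fewer than ``min_valid_days`` valid days are dropped.
    ``month_index`` counts calendar months since each person's first valid
    month (gaps leave holes, handled downstream by carry-forward).
    """
    config = config or CurationConfig()
    cols = ["person_id", "month", "month_index", "mean_steps",
            "n_valid_days", "first_valid_date"]
    if valid_days.empty:
        return pd.DataFrame(columns=cols)
    df = valid_days.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["month"] = df["date"].dt.to_period("M")
    g = df.groupby(["person_id", "month"], sort=True)
    out = g.agg(
        mean_steps=("steps", "mean"),
        n_valid_days=("steps", "size"),
        first_valid_date=("date", "min"),
    ).reset_index()
    out = out[out["n_valid_days"] >= config.min_valid_days].copy()
    first_month = out.groupby("person_id")["month"].transform("min")
    out["month_index"] = (out["month"] - first_month).apply(lambda p: p.n)
    return out[cols].reset_index(drop=True)


def _baseline_bmi(person_bmi: pd.DataFrame, t0: pd.Timestamp, window_days: float):
    """BMI record closest to monitoring start within +/- window; NaN if none."""
    delta = (pd.to_datetime(person_bmi["date"]) - t0).dt.days.abs()
    eligible = person_bmi.loc[delta <= window_days]
    if eligible.empty:
        return np.nan
    return float(eligible.loc[delta.loc[eligible.index].idxmin(), "bmi"])


def assemble_cohort(
    monthly: pd.DataFrame,
    bmi: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    config: CurationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Build the analytic cohort with the incident-obesity landmark.

    Time zero is each person's first valid monitoring day.  A person enters
    the cohort when they have at least one exposure month and a baseline BMI
    record (< 30) within the configured window; the event is the first BMI
    record >= 30 at or after the landmark.  A first BMI >= 30 *before* the
    landmark excludes the person entirely.  Censoring time is the later of
    the last exposure-month end and the last BMI record.

    Returns (cohort, exposure, attrition).  ``exposure`` adds analysis-time
    columns t_start/t_stop (years from time zero) per retained person-month.
    """
    config = config or CurationConfig()
    config.validate()
    bmi = bmi.copy()
    bmi["date"] = pd.to_datetime(bmi["date"])
    monthly = monthly.copy()

    all_persons = sorted(set(monthly["person_id"]) | set(bmi["person_id"]))
    attrition = {
        "input_persons": len(all_persons),
        "no_exposure_months": 0,
        "no_baseline_bmi": 0,
        "baseline_obese": 0,
        "event_before_landmark": 0,
        "nonpositive_followup": 0,
        "analytic_persons": 0,
    }
    exclusions: dict[str, str] = {}

    rows = []
    bmi_by_person = dict(tuple(bmi.groupby("person_id")))
    monthly_by_person = dict(tuple(monthly.groupby("person_id")))
    for pid in all_persons:
        pm = monthly_by_person.get(pid)
        if pm is None or pm.empty:
            attrition["no_exposure_months"] += 1
            exclusions[pid] = "no_exposure_months"
            continue
        pm = pm.sort_values("month_index")
        t0 = pd.to_datetime(pm["first_valid_date"].iloc[0])
        pb = bmi_by_person.get(pid)
        if pb is None or pb.empty:
            attrition["no_baseline_bmi"] += 1
            exclusions[pid] = "no_baseline_bmi"
            continue
        pb = pb.sort_values("date")
        base_bmi = _baseline_bmi(pb, t0, config.baseline_window_days)
        if not np.isfinite(base_bmi):
            attrition["no_baseline_bmi"] += 1
            exclusions[pid] = "no_baseline_bmi"
            continue
        if base_bmi >= config.obesity_bmi:
            attrition["baseline_obese"] += 1
            exclusions[pid] = "baseline_obese"
            continue

        t_years = (pb["date"] - t0).dt.days / DAYS_PER_YEAR
        obese = pb["bmi"] >= config.obesity_bmi
        post = obese & (t_years > 0)
        if post.any():
            first_obese_t = float(t_years[post].min())
            if first_obese_t < config.landmark_years:
                attrition["event_before_landmark"] += 1
                exclusions[pid] = "event_before_landmark"
                continue
            event, event_time = True, first_obese_t
        else:
            event, event_time = False, np.nan

        last_month_end = (pm["month"].max() + 1).to_timestamp()
        last_bmi_date = pb["date"].max()
        censor = max(
            (last_month_end - t0).days / DAYS_PER_YEAR,
            (last_bmi_date - t0).days / DAYS_PER_YEAR,
        )
        time = event_time if event else censor
        if not np.isfinite(time) or time <= 0:
            attrition["nonpositive_followup"] += 1
            exclusions[pid] = "nonpositive_followup"
            continue
        first_month = pm.iloc[0]
        rows.append({
            "person_id": pid,
            "t0": t0,
            "baseline_bmi": base_bmi,
            "baseline_steps": float(first_month["mean_steps"]),
            "event": bool(event),
            "time": float(time),
        })

    cohort = pd.DataFrame(rows, columns=["person_id", "t0", "baseline_bmi",
                                         "baseline_steps", "event", "time"])
    attrition["analytic_persons"] = len(cohort)

    if covariates is not None and not cohort.empty:
        cov = covariates.drop(columns=["baseline_bmi"], errors="ignore")
        cohort = cohort.merge(cov, on="person_id", how="left")
        if "age" in cohort.columns:
            cohort = cohort.rename(columns={"age": "baseline_age"})

    keep = set(cohort["person_id"])
    exposure = monthly[monthly["person_id"].isin(keep)].copy()
    if not exposure.empty:
        t0_map = cohort.set_index("person_id")["t0"]
        month_start = exposure["month"].dt.to_timestamp()
        month_end = (exposure["month"] + 1).dt.to_timestamp()
        t0s = exposure["person_id"].map(t0_map)
        exposure["t_start"] = np.maximum(
            0.0, (month_start - t0s).dt.days / DAYS_PER_YEAR
        )
        exposure["t_stop"] = (month_end - t0s).dt.days / DAYS_PER_YEAR
    attrition["exclusion_reasons"] = exclusions
    return cohort, exposure, attrition
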