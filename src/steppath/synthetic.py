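"""Synthetic cohorts with a known obesity-hazard model.

Emulates the data streams the analysis consumes: daily wearable step
counts with wear-time artifacts, encounter-driven BMI documentation in
an EHR-like record, polygenic scores with ancestry-PC loadings, and
baseline covariates with missingness.  Obesity onset is drawn from a
piecewise-constant proportional-hazards model whose exposure is the
person's mean daily steps in each month of monitoring, so parameter
recovery by the downstream time-varying Cox fit is a well-posed check.

Time is measured in years from each person's monitoring start; monitoring
starts are aligned to calendar-month boundaries by default so that the
generator's person-month hazard intervals coincide with the calendar-month
aggregation used downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

EPOCH = np.datetime64("2018-01-01")
DAYS_PER_YEAR = 365.25

# education levels, highest attained
EDU_LEVELS = ("college", "some_college", "no_college")

#: covariates eligible for injected missingness (the ones imputed downstream)
MISSING_ELIGIBLE = ("sbp", "alcohol", "education", "smoking")


@dataclass
class SimulationConfig:
    """True-model parameters for a synthetic cohort.

    The hazard of obesity onset for person *i* in month *m* is

        lambda_im = baseline_hazard_rate
                    * exp(beta_prs * PRS_i
                          + beta_steps * steps_im / 1000
                          + beta_steps_quadratic * (steps_im/1000 - 8)^2
                          + sum_c beta_covariates[c] * Z_ic)

    with ``steps_im`` the person's true mean daily steps in month *m* and
    ``Z`` the centred covariate codings described in :func:`covariate_design`.
    ``baseline_hazard_rate`` is therefore the rate (events per person-year)
    at zero steps and centred covariates; the default is chosen so the
    annual incidence at the median step count (~8000/day) is roughly 4%.
    """

    n_participants: int = 1000
    follow_up_years: float = 5.0
    seed: int = 0
    baseline_hazard_rate: float = 0.98
    beta_prs: float = 0.5
    beta_steps: float = -0.4
    beta_steps_quadratic: float = 0.0
    beta_covariates: dict = field(default_factory=lambda: {
        "age": 0.01,        # per year above 50
        "sex_male": 0.2,
        "cancer": 0.0,
        "cad": 0.0,
        "sbp": 0.005,       # per mm Hg above 125
        "alcohol": 0.0,
        "education_some_college": 0.0,
        "education_no_college": 0.0,
        "baseline_bmi": 0.0,  # per BMI unit above 25
    })
    step_log_mean: float = math.log(8300.0)
    step_between_sd: float = 0.35
    step_within_sd: float = 0.25
    #: mixture weights (high-wear, low-wear) over day types; low-wear days
    #: fall below the 10-hour wear threshold and are dropped by curation
    wear_hour_distribution: tuple = (0.92, 0.08)
    #: fraction of days with device artifacts outside [100, 45000] steps
    artifact_low_rate: float = 0.005
    artifact_high_rate: float = 0.001
    encounter_rate: float = 2.0      # clinic visits with a BMI per year
    documentation_only: bool = True  # event observed at first post-onset encounter
    missing_rate: float = 0.05       # MCAR probability per eligible covariate
    missing_variables: tuple = MISSING_ELIGIBLE
    mar_on_age: bool = False         # missingness in SBP depends on age instead
    baseline_bmi_mean: float = 25.5
    baseline_bmi_sd: float = 2.0
    pc_loadings: tuple = (0.2, 0.2)  # raw-score loading on the first PCs
    n_pcs: int = 10
    n_snps: int = 20
    emit_daily_records: bool = True  # False skips the daily CSV-sized frame

    def validate(self) -> None:
        numeric = {
            "n_participants": self.n_participants,
            "follow_up_years": self.follow_up_years,
            "baseline_hazard_rate": self.baseline_hazard_rate,
            "beta_prs": self.beta_prs,
            "beta_steps": self.beta_steps,
            "step_log_mean": self.step_log_mean,
            "step_between_sd": self.step_between_sd,
            "step_within_sd": self.step_within_sd,
            "encounter_rate": self.encounter_rate,
            "missing_rate": self.missing_rate,
        }
        for name, value in {**numeric, **self.beta_covariates}.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite parameter: {name}={value!r}")
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.follow_up_years < 1:
            raise ValueError("follow_up_years < 1: the 6-month landmark is undefined")
        if self.baseline_hazard_rate < 0 or self.encounter_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.step_within_sd < 0 or self.step_between_sd < 0:
            raise ValueError("step SDs must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        w = np.asarray(self.wear_hour_distribution, dtype=float)
        if w.min() < 0 or not np.isclose(w.sum(), 1.0):
            raise ValueError("wear_hour_distribution must be nonnegative weights summing to 1")


@dataclass
class SyntheticCohort:
    """Container for one generated cohort plus its ground truth."""

    steps: pd.DataFrame        # person_id, date, steps, wear_minutes
    bmi: pd.DataFrame          # person_id, date, bmi
    genetics: pd.DataFrame     # person_id, score, pc1..pc10
    dosages: pd.DataFrame      # person_id, snp_0..; raw allele dosages in [0,2]
    snp_weights: pd.DataFrame  # snp_id, weight
    covariates: pd.DataFrame   # person_id, age, sex, cancer, cad, sbp, alcohol, education, smoking, baseline_bmi
    truth: pd.DataFrame        # person_id, prs_true, latent_onset_time (NaN if none)
    config: SimulationConfig
    monthly_true_steps: np.ndarray  # (n, months) true mean daily steps
    month_bounds_years: np.ndarray | None = None  # (n, months+1) interval bounds

    def write_csvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.steps.to_csv(outdir / "steps.csv", index=False)
        self.bmi.to_csv(outdir / "bmi.csv", index=False)
        self.genetics.to_csv(outdir / "genetics.csv", index=False)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        self.dosages.to_csv(outdir / "dosages.csv", index=False)
        self.snp_weights.to_csv(outdir / "snp_weights.csv", index=False)
        truth = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "participants": self.truth.to_dict(orient="records"),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=float))


def covariate_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Centred covariate codings entering the true log-hazard.

    age and SBP are centred (50 years, 125 mm Hg), baseline BMI at 25;
    sex/cancer/CAD/alcohol/smoking are 0/1; education enters as two
    indicators against the 'college' reference.
    """
    z = pd.DataFrame(index=cov.index)
    z["age"] = cov["age"] - 50.0
    z["sex_male"] = (cov["sex"] == "male").astype(float)
    z["cancer"] = cov["cancer"].astype(float)
    z["cad"] = cov["cad"].astype(float)
    z["sbp"] = cov["sbp"] - 125.0
    z["alcohol"] = cov["alcohol"].astype(float)
    z["education_some_college"] = (cov["education"] == "some_college").astype(float)
    z["education_no_college"] = (cov["education"] == "no_college").astype(float)
    z["baseline_bmi"] = cov["baseline_bmi"] - 25.0
    return z


def simulate_step_series(person_params: dict, horizon: float, seed) -> pd.DataFrame:
    """Daily step records for one person over ``horizon`` years.

    ``person_params`` carries ``log_intercept``, ``within_sd``, wear-mixture
    weights and artifact rates (missing keys fall back to config defaults).
    Returned records include wear-time and step artifacts so day-level
    curation filters have something to remove.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_days = int(round(horizon * DAYS_PER_YEAR))
    p = dict(person_params)
    log_int = p["log_intercept"]
    within = p.get("within_sd", 0.25)
    wear_w = p.get("wear_hour_distribution", (0.92, 0.08))
    lo_rate = p.get("artifact_low_rate", 0.0)
    hi_rate = p.get("artifact_high_rate", 0.0)
    start = p.get("start_date", EPOCH)

    steps_true = np.exp(log_int + within * rng.standard_normal(n_days))
    steps = np.rint(steps_true).astype(np.int64)
    low_wear = rng.random(n_days) < wear_w[1]
    wear = np.where(
        low_wear,
        rng.uniform(60, 590, n_days),
        np.clip(rng.normal(870, 90, n_days), 600, 1440),
    )
    u = rng.random(n_days)
    steps = np.where(u < lo_rate, rng.integers(0, 100, n_days), steps)
    steps = np.where(u > 1 - hi_rate, rng.integers(45001, 70000, n_days), steps)
    dates = np.asarray(start, dtype="datetime64[D]") + np.arange(n_days)
    return pd.DataFrame({
        "person_id": p.get("person_id", "P0"),
        "date": dates,
        "steps": steps,
        "wear_minutes": np.rint(wear).astype(np.int64),
    })


def _month_boundaries(start: np.datetime64, n_months: int) -> np.ndarray:
    """Calendar month starts from ``start`` (itself a month boundary)."""
    m0 = start.astype("datetime64[M]")
    return (m0 + np.arange(n_months + 1)).astype("datetime64[D]")


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort under the configured true hazard model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_months = int(round(config.follow_up_years * 12))
    person_ids = np.array([f"P{i:05d}" for i in range(n)])

    # ---- monitoring start: a calendar-month boundary in the first year
    start_month = rng.integers(0, 12, n)
    starts = (EPOCH.astype("datetime64[M]") + start_month).astype("datetime64[D]")

    # ---- genetics: dosages -> raw score with PC loadings
    maf = rng.uniform(0.1, 0.9, config.n_snps)
    dosage = rng.binomial(2, maf, size=(n, config.n_snps)).astype(float)
    weights = rng.normal(0.0, 0.1, config.n_snps)
    raw_core = dosage @ weights
    prs_core = (raw_core - raw_core.mean()) / raw_core.std()
    pcs = rng.standard_normal((n, config.n_pcs))
    score = prs_core.copy()
    for j, loading in enumerate(config.pc_loadings):
        if j < config.n_pcs:
            score = score + loading * pcs[:, j]

    # ---- baseline covariates
    cov = pd.DataFrame({
        "person_id": person_ids,
        "age": np.clip(rng.normal(50, 13, n), 18.5, 85).round(1),
        "sex": np.where(rng.random(n) < 0.27, "male", "female"),
        "cancer": (rng.random(n) < 0.23).astype(int),
        "cad": (rng.random(n) < 0.03).astype(int),
        "sbp": np.clip(rng.normal(125, 15, n), 85, 200).round(0),
        "alcohol": (rng.random(n) < 0.98).astype(int),
        "education": rng.choice(EDU_LEVELS, n, p=[0.78, 0.18, 0.04]),
        "smoking": (rng.random(n) < 0.32).astype(int),
        "baseline_bmi": np.clip(
            rng.normal(config.baseline_bmi_mean, config.baseline_bmi_sd, n), 17, 34
        ).round(1),
    })
    z = covariate_design(cov)
    eta_fixed = config.beta_prs * prs_core
    for name, beta in config.beta_covariates.items():
        if beta != 0.0:
            eta_fixed = eta_fixed + beta * z[name].to_numpy()

    # ---- daily behavioural steps and monthly true exposure
    intercepts = config.step_log_mean + config.step_between_sd * rng.standard_normal(n)
    bounds = [_month_boundaries(s, n_months) for s in starts]
    month_days = np.array([np.diff(b).astype(int) for b in bounds])  # (n, months)
    total_days = month_days.sum(axis=1)
    max_days = total_days.max()

    monthly_true = np.empty((n, n_months))
    steps_frames = []
    # per-person daily draws; one RNG stream keeps record-level determinism
    for i in range(n):
        nd = total_days[i]
        log_day = intercepts[i] + config.step_within_sd * rng.standard_normal(nd)
        true_daily = np.exp(log_day)
        # month-wise true mean of the behavioural (artifact-free) process
        idx = np.repeat(np.arange(n_months), month_days[i])
        sums = np.bincount(idx, weights=true_daily, minlength=n_months)
        monthly_true[i] = sums / month_days[i]

        if config.emit_daily_records:
            steps_obs = np.rint(true_daily).astype(np.int64)
            low_wear = rng.random(nd) < config.wear_hour_distribution[1]
            wear = np.where(
                low_wear,
                rng.uniform(60, 590, nd),
                np.clip(rng.normal(870, 90, nd), 600, 1440),
            )
            u = rng.random(nd)
            steps_obs = np.where(u < config.artifact_low_rate,
                                 rng.integers(0, 100, nd), steps_obs)
            steps_obs = np.where(u > 1 - config.artifact_high_rate,
                                 rng.integers(45001, 70000, nd), steps_obs)
            steps_frames.append(pd.DataFrame({
                "person_id": person_ids[i],
                "date": starts[i] + np.arange(nd),
                "steps": steps_obs,
                "wear_minutes": np.rint(wear).astype(np.int64),
            }))
        else:
            # keep the RNG stream aligned across emit modes
            rng.random(nd)
            rng.normal(870, 90, nd)
            rng.random(nd)
            rng.integers(0, 100, nd)
            rng.integers(45001, 70000, nd)

    # ---- latent obesity onset from the piecewise-constant hazard
    steps_k = monthly_true / 1000.0
    eta = eta_fixed[:, None] + config.beta_steps * steps_k
    if config.beta_steps_quadratic != 0.0:
        eta = eta + config.beta_steps_quadratic * (steps_k - 8.0) ** 2
    lam = config.baseline_hazard_rate * np.exp(eta)          # (n, months), per year
    month_len_years = month_days / DAYS_PER_YEAR
    cum_haz = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(lam * month_len_years, axis=1)], axis=1
    )
    e_draw = rng.exponential(1.0, n)
    onset = np.full(n, np.nan)
    month_starts_years = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(month_len_years, axis=1)], axis=1
    )
    for i in range(n):
        k = np.searchsorted(cum_haz[i], e_draw[i], side="right") - 1
        if k < n_months:
            onset[i] = month_starts_years[i, k] + (e_draw[i] - cum_haz[i, k]) / lam[i, k]

    # ---- encounter process and BMI documentation
    bmi_frames = []
    for i in range(n):
        t_base = rng.uniform(-0.3, 0.05)
        n_enc = rng.poisson(config.encounter_rate * config.follow_up_years)
        t_enc = np.sort(rng.uniform(0.0, config.follow_up_years, n_enc))
        times = np.concatenate([[t_base], t_enc])
        if not config.documentation_only and np.isfinite(onset[i]):
            times = np.sort(np.concatenate([times, [onset[i]]]))
        pre = ~np.isfinite(onset[i]) | (times < onset[i])
        noise = rng.normal(0, 0.5, times.size)
        bmi_val = np.where(
            pre,
            np.minimum(cov.loc[i, "baseline_bmi"] + noise, 29.8),
            30.0 + np.abs(rng.normal(0.8, 1.0, times.size)),
        )
        dates = starts[i] + np.rint(times * DAYS_PER_YEAR).astype(int)
        bmi_frames.append(pd.DataFrame({
            "person_id": person_ids[i],
            "date": dates.astype("datetime64[D]"),
            "bmi": np.round(bmi_val, 1),
        }))

    # ---- covariate missingness
    cov_obs = cov.copy()
    for name in config.missing_variables:
        if config.mar_on_age and name == "sbp":
            p_miss = 1.0 / (1.0 + np.exp(-((cov["age"] - 50) / 10.0 - 1.5)))
        else:
            p_miss = np.full(n, config.missing_rate)
        mask = rng.random(n) < p_miss
        cov_obs.loc[mask, name] = np.nan

    steps_df = (pd.concat(steps_frames, ignore_index=True)
                if steps_frames else
                pd.DataFrame(columns=["person_id", "date", "steps", "wear_minutes"]))
    genetics = pd.DataFrame({"person_id": person_ids, "score": score})
    for j in range(config.n_pcs):
        genetics[f"pc{j + 1}"] = pcs[:, j]
    dosage_df = pd.DataFrame(dosage, columns=[f"snp_{j}" for j in range(config.n_snps)])
    dosage_df.insert(0, "person_id", person_ids)
    truth = pd.DataFrame({
        "person_id": person_ids,
        "prs_true": prs_core,
        "latent_onset_time": onset,
        # the Exp(1) draw behind each onset, so an external inverse-CDF
        # oracle can reproduce the sampler from the same randomness
        "exp_draw": e_draw,
    })
    return SyntheticCohort(
        steps=steps_df,
        bmi=pd.concat(bmi_frames, ignore_index=True),
        genetics=genetics,
        dosages=dosage_df,
        snp_weights=pd.DataFrame({
            "snp_id": [f"snp_{j}" for j in range(config.n_snps)],
            "weight": weights,
        }),
        covariates=cov_obs,
        truth=truth,
        config=config,
        monthly_true_steps=monthly_true,
        month_bounds_years=month_starts_years,
    )


def analysis_frames(
    cohort: SyntheticCohort,
    landmark_years: float = 0.5,
    exclude_baseline_obese: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analytic cohort and exposure frames straight from the ground truth.

    Bypasses record-level curation (daily filters, encounter-driven BMI
    documentation): the event is the latent onset itself and the exposure
    is the true monthly mean.  This is the right substrate for parameter-
    recovery studies, where the estimand is the generating model and the
    observation layer would only add orthogonal noise; record-level
    behaviour is exercised by the curation stage on the same cohorts.
    """
    from .genetics import build_score_set

    cfg = cohort.config
    onset = cohort.truth["latent_onset_time"].to_numpy()
    event = np.isfinite(onset)
    time = np.where(event, onset, cfg.follow_up_years)
    keep = ~(event & (onset < landmark_years))
    cov = cohort.covariates
    if exclude_baseline_obese:
        keep &= ~(cov["baseline_bmi"].fillna(0) >= 30).to_numpy()
    scores = build_score_set(cohort.genetics)

    frame = cov.loc[keep].rename(columns={"age": "baseline_age"}).copy()
    frame["baseline_steps"] = cohort.monthly_true_steps[keep, 0]
    frame["event"] = event[keep]
    frame["time"] = time[keep]
    frame = frame.merge(
        scores[["person_id", "prs_residual", "percentile"]], on="person_id")

    n, n_months = cohort.monthly_true_steps.shape
    idx = np.flatnonzero(keep)
    bounds = cohort.month_bounds_years
    exposure = pd.DataFrame({
        "person_id": np.repeat(cov["person_id"].to_numpy()[idx], n_months),
        "month_index": np.tile(np.arange(n_months), idx.size),
        "mean_steps": cohort.monthly_true_steps[idx].ravel(),
        "n_valid_days": 30,
        "t_start": bounds[idx, :-1].ravel(),
        "t_stop": bounds[idx, 1:].ravel(),
    })
    return frame.reset_index(drop=True), exposure
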