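"""Multiple imputation by bootstrap plus predictive mean matching (PMM),
with Rubin's rules for pooling Cox fits across completed datasets.

Missingness in this analysis is confined to baseline covariates (systolic
blood pressure, alcohol use, educational level, smoking, baseline BMI),
so imputation operates on the person-level cohort table; each completed
cohort is then expanded to counting-process form and fitted.  PMM never
invents values: a missing entry is replaced by the *observed* value of a
donor whose predicted mean is among the k nearest, which keeps imputed
categorical codes valid and continuous values within the empirical
support.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .cox import ModelFit, ModelSpec, build_counting_process, fit_cox_tv

#: variables eligible for imputation (the EHR-derived baseline measures)
IMPUTABLE = ("baseline_bmi", "alcohol", "education", "sbp", "smoking")

#: default predictors used in the imputation models
_PREDICTORS = ("baseline_age", "sex", "baseline_steps", "prs_residual",
               "event", "time", "cancer", "cad")


def _numeric_frame(df: pd.DataFrame, cols) -> pd.DataFrame:
    """Numeric encoding (category codes for object columns), mean-filled."""
    out = pd.DataFrame(index=df.index)
    for c in cols:
        if c not in df.columns:
            continue
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            col = pd.Categorical(col).codes.astype(float)
            col = pd.Series(col, index=df.index).replace(-1, np.nan)
        else:
            col = pd.to_numeric(col, errors="coerce")
        out[c] = col.fillna(col.mean())
    return out


def pmm_impute(
    cohort: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    k_donors: int = 5,
    variables: tuple = IMPUTABLE,
    predictors: tuple = _PREDICTORS,
) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of the cohort.

    For each round and each variable with missing entries: draw a bootstrap
    sample of the rows observed on that variable, fit a linear model of the
    (numerically coded) target on the predictors, and fill each missing
    entry with the observed value of a random one of the ``k_donors``
    bootstrap donors closest in predicted mean.  Categorical targets are
    matched on the same predicted score of their numeric coding.

    With no missingness the output equals the input for every round.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    variables = [v for v in variables if v in cohort.columns]
    for v in variables:
        if cohort[v].isna().all():
            raise ValueError(f"variable {v!r} is entirely missing")
        frac = cohort[v].isna().mean()
        if frac > 0.5:
            import warnings
            warnings.warn(f"variable {v!r} is {frac:.0%} missing", stacklevel=2)

    pred_frame = _numeric_frame(cohort, predictors)
    X_all = np.column_stack([np.ones(len(cohort)), pred_frame.to_numpy(dtype=float)])

    completed = []
    for _ in range(m):
        filled = cohort.copy()
        for v in variables:
            miss = cohort[v].isna().to_numpy()
            if not miss.any():
                continue
            obs_idx = np.flatnonzero(~miss)
            # numeric coding of the target for the working linear model
            target = cohort[v]
            if target.dtype == object or isinstance(target.dtype, pd.CategoricalDtype):
                y_num = pd.Series(
                    pd.Categorical(target).codes.astype(float), index=cohort.index
                ).replace(-1, np.nan).to_numpy()
            else:
                y_num = pd.to_numeric(target, errors="coerce").to_numpy(dtype=float)
            boot = rng.choice(obs_idx, size=obs_idx.size, replace=True)
            coef, *_ = np.linalg.lstsq(X_all[boot], y_num[boot], rcond=None)
            pred = X_all @ coef
            donor_pool = np.unique(boot)  # donors present in the bootstrap sample
            donor_pred = pred[donor_pool]
            order = np.argsort(donor_pred, kind="stable")
            donor_sorted = donor_pool[order]
            pred_sorted = donor_pred[order]
            for i in np.flatnonzero(miss):
                pos = np.searchsorted(pred_sorted, pred[i])
                lo = max(0, pos - k_donors)
                hi = min(donor_sorted.size, pos + k_donors)
                window = donor_sorted[lo:hi]
                dist = np.abs(pred_sorted[lo:hi] - pred[i])
                nearest = window[np.argsort(dist, kind="stable")[:k_donors]]
                donor = nearest[rng.integers(0, nearest.size)]
                filled.iloc[i, filled.columns.get_loc(v)] = cohort.iloc[donor][v]
        completed.append(filled)
    return completed


def pool_fits(fits: list[ModelFit]) -> ModelFit:
    """Rubin's rules across multiply imputed fits.

    Pooled coefficients are the mean; total variance is the mean
    within-imputation covariance plus (1 + 1/m) times the between-imputation
    covariance.  Per-coefficient Barnard-Rubin degrees of freedom are stored
    in ``meta['df']`` (infinite when m = 1, with a warning).
    """
    if not fits:
        raise ValueError("no fits to pool")
    first = fits[0]
    for f in fits[1:]:
        if f.term_map != first.term_map or f.names != first.names:
            raise ValueError("fits have mismatched term maps")
    m = len(fits)
    betas = np.stack([f.beta for f in fits])
    pooled = betas.mean(axis=0)
    within = np.mean([f.cov for f in fits], axis=0)
    if m == 1:
        import warnings
        warnings.warn("pooling a single imputation: between-variance is zero")
        between = np.zeros_like(within)
    else:
        dev = betas - pooled
        between = dev.T @ dev / (m - 1)
    total = within + (1 + 1 / m) * between

    with np.errstate(divide="ignore", invalid="ignore"):
        b_diag = np.diag(between)
        t_diag = np.diag(total)
        r = (1 + 1 / m) * b_diag / np.diag(within)
        df_old = (m - 1) * (1 + 1 / np.where(r > 0, r, np.inf)) ** 2
        # Barnard-Rubin small-sample correction using the complete-data df
        n_events = first.n_events
        p = pooled.shape[0]
        df_com = max(n_events - p, 1)
        lam = (1 + 1 / m) * b_diag / t_diag
        df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
        df = np.where(b_diag > 0, 1 / (1 / df_old + 1 / df_obs), np.inf)

    meta = dict(first.meta)
    meta["df"] = df
    meta["m"] = m
    meta["between_diag"] = b_diag
    meta["within_diag"] = np.diag(within)
    return ModelFit(
        beta=pooled,
        cov=total,
        loglik=float(np.mean([f.loglik for f in fits])),
        names=list(first.names),
        term_map=dict(first.term_map),
        n_events=first.n_events,
        spec=first.spec,
        meta=meta,
    )


def pooled_confint(fit: ModelFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-coefficient CIs using the Barnard-Rubin t reference when pooled."""
    se = fit.se()
    df = fit.meta.get("df")
    if df is None:
        q = stats.norm.ppf(1 - alpha / 2) * np.ones_like(se)
    else:
        q = np.where(np.isfinite(df), stats.t.ppf(1 - alpha / 2, np.maximum(df, 1)),
                     stats.norm.ppf(1 - alpha / 2))
    return pd.DataFrame({
        "term": fit.names,
        "coef": fit.beta,
        "se": se,
        "low": fit.beta - q * se,
        "high": fit.beta + q * se,
    })


def fit_multiply_imputed(
    cohort: pd.DataFrame,
    exposure: pd.DataFrame,
    spec_builder,
    m: int = 10,
    seed: int = 0,
    k_donors: int = 5,
) -> tuple[ModelFit, list[ModelFit]]:
    """Impute, expand each completed cohort, fit, and pool.

    ``spec_builder`` maps a counting-process frame to a :class:`ModelSpec`
    (so knot placement can react to each completed dataset; the first
    completed dataset's spec is reused for the rest to keep the term map
    aligned, as pooling requires).
    """
    completed = pmm_impute(cohort, m=m, seed=seed, k_donors=k_donors)
    skeleton = build_counting_process(cohort, exposure, covariate_cols=[])
    cov_cols = [c for c in cohort.columns
                if c not in ("person_id", "t0", "event", "time")]
    fits = []
    spec: ModelSpec | None = None
    for c in completed:
        cp = skeleton.merge(c[["person_id"] + cov_cols], on="person_id", how="left")
        if spec is None:
            spec = spec_builder(cp)
        fits.append(fit_cox_tv(cp, spec))
    return pool_fits(fits), fits
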