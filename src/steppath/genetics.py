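"""Polygenic score handling: scoring, PC residualization, percentiles,
and incremental Nagelkerke R-squared.

The score itself is a weighted allele-dosage sum.  Because polygenic
scores capture ancestry as well as trait liability, the score is
regressed on the leading genetic principal components and the residual
is carried forward; percentiles are cohort-internal ranks of that
residual.  Incremental Nagelkerke R2 quantifies how much variance in
binary obesity status the score explains beyond age, sex, and the PCs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


def score_genotypes(dosages: np.ndarray | pd.DataFrame, weights: np.ndarray | pd.Series) -> np.ndarray:
    """Weighted dosage sum per person: score_i = sum_j dosage_ij * weight_j.

    Dosages are allele counts in [0, 2]; missing dosages are mean-imputed
    per SNP (the standard scoring convention).
    """
    d = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.ndim != 2 or d.shape[1] != w.shape[0]:
        raise ValueError(
            f"dosage matrix has {d.shape[1] if d.ndim == 2 else '?'} SNPs "
            f"but {w.shape[0]} weights"
        )
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d = d.copy()
        d[idx] = np.take(col_mean, idx[1])
    return d @ w


def residualize_scores(raw_scores: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    """OLS residuals of the raw score on the PCs plus an intercept.

    Residuals are orthogonal to every PC column and have zero mean.
    A rank-deficient PC matrix is rejected with the offending columns named.
    """
    y = np.asarray(raw_scores, dtype=float)
    p = np.asarray(pcs, dtype=float)
    if p.ndim != 2 or y.shape[0] != p.shape[0]:
        raise ValueError("scores and PC matrix must have matching rows")
    n, k = p.shape
    if n < k + 2:
        raise ValueError(f"need more persons ({n}) than predictors ({k + 1})")
    x = np.column_stack([np.ones(n), p])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name PC columns that add no rank beyond the preceding ones
        bad = []
        r = 1
        for j in range(k):
            rj = np.linalg.matrix_rank(x[:, : j + 2])
            if rj == r:
                bad.append(f"pc{j + 1}")
            r = rj
        raise ValueError(f"rank-deficient PC matrix; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def prs_percentiles(residuals: np.ndarray) -> np.ndarray:
    """Rank-based percentiles in (0, 100), ties averaged (Hazen-type)."""
    r = np.asarray(residuals, dtype=float)
    ranks = stats.rankdata(r, method="average")
    return 100.0 * (ranks - 0.5) / r.shape[0]


def build_score_set(genetics: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """From a genetics table (person_id, score, pc1..pcK) to the analysis-
    ready score set: residualized (optionally standardized) score plus
    cohort-internal percentile."""
    pc_cols = [c for c in genetics.columns if c.startswith("pc")]
    resid = residualize_scores(
        genetics["score"].to_numpy(), genetics[pc_cols].to_numpy()
    )
    if standardize:
        resid = resid / resid.std(ddof=0)
    return pd.DataFrame({
        "person_id": genetics["person_id"],
        "raw_score": genetics["score"],
        "prs_residual": resid,
        "percentile": prs_percentiles(resid),
    })


def _nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_null)
    return cox_snell / max_cs


def _fit_logit(y, x):
    model = sm.Logit(y, x)
    try:
        res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=False)
    except Exception as exc:  # noqa: BLE001 - convergence/separation
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
    return res


def incremental_nagelkerke(
    outcome: np.ndarray,
    prs: np.ndarray,
    covariates: np.ndarray | pd.DataFrame,
) -> dict:
    """Nagelkerke R2 gained by adding the PRS to a logistic model of
    obesity status on the covariates (age, sex, PCs, ...).

    Fits full (covariates + PRS) and subset (covariates only) logistic
    regressions by Newton-Raphson ML; R2_N = CoxSnell / max(CoxSnell)
    with the intercept-only log-likelihood as the null.  Returns the
    increment together with the PRS coefficient and its Wald p-value.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    cov = np.asarray(covariates, dtype=float)
    n = y.shape[0]
    x_sub = sm.add_constant(cov, has_constant="add")
    x_full = np.column_stack([x_sub, np.asarray(prs, dtype=float)])
    if np.linalg.matrix_rank(x_full) == np.linalg.matrix_rank(x_sub):
        # the score is collinear with the covariates: no added information
        res_sub = _fit_logit(y, x_sub)
        ll_null = sm.Logit(y, np.ones((n, 1))).fit(disp=False).llf
        r2 = _nagelkerke(res_sub.llf, ll_null, n)
        return {"r2_full": float(r2), "r2_subset": float(r2), "increment": 0.0,
                "prs_beta": float("nan"), "prs_p": float("nan")}

    res_full = _fit_logit(y, x_full)
    res_sub = _fit_logit(y, x_sub)
    ll_null = sm.Logit(y, np.ones((n, 1))).fit(disp=False).llf
    r2_full = _nagelkerke(res_full.llf, ll_null, n)
    r2_sub = _nagelkerke(res_sub.llf, ll_null, n)
    return {
        "r2_full": float(r2_full),
        "r2_subset": float(r2_sub),
        "increment": float(r2_full - r2_sub),
        "prs_beta": float(res_full.params[-1]),
        "prs_p": float(res_full.pvalues[-1]),
    }
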