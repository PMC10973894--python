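"""Time-varying Cox regression on counting-process data.

The exposure (monthly mean daily steps) changes within person, so the
partial likelihood is evaluated on (start, stop] intervals: a row is at
risk at an event time t iff start < t <= stop.  Ties are handled with the
Efron correction.  Continuous covariates may enter as restricted cubic
splines with 3 knots; a nonlinear term that fails its Wald test is
dropped back to linear.  The genetic score interacts with the step-count
spline columns (linear-PRS x steps block), giving the 2-df interaction
chunk test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .splines import rcs_basis, rcs_knots

DAYS_PER_YEAR = 365.25


class ConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# model specification and design construction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TermSpec:
    """One model term: a linear column, a 3-knot RCS block, or indicators."""

    name: str
    kind: str = "linear"              # 'linear' | 'rcs' | 'categorical'
    knots: tuple | None = None        # rcs only; on the scaled variable
    levels: tuple | None = None       # categorical only; non-reference levels
    scale: float = 1.0                # raw value is divided by this

    def columns(self) -> list[str]:
        if self.kind == "linear":
            return [self.name]
        if self.kind == "rcs":
            return [self.name, self.name + "'"]
        return [f"{self.name}[{lv}]" for lv in self.levels]


@dataclass(frozen=True)
class ModelSpec:
    terms: tuple
    # (prs_term_name, steps_term_name): linear PRS x all steps columns
    interaction: tuple | None = None

    def term(self, name: str) -> TermSpec:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def with_linear(self, name: str) -> "ModelSpec":
        terms = tuple(
            replace(t, kind="linear", knots=None) if t.name == name else t
            for t in self.terms
        )
        return replace(self, terms=terms)

    def column_names(self) -> list[str]:
        names: list[str] = []
        for t in self.terms:
            names.extend(t.columns())
        if self.interaction is not None:
            prs, steps = self.interaction
            for c in self.term(steps).columns():
                names.append(f"{prs}:{c}")
        return names


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix, column names, and a term map of name -> column indices.

    The term map addresses each variable's block plus, where present,
    ``{name}_nonlinear`` (the RCS curvature column) and ``interaction``.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    term_map: dict[str, list[int]] = {}
    col = 0
    steps_block: np.ndarray | None = None
    for t in spec.terms:
        if t.kind == "linear":
            x = df[t.name].to_numpy(dtype=float) / t.scale
            block = x[:, None]
        elif t.kind == "rcs":
            x = df[t.name].to_numpy(dtype=float) / t.scale
            block = rcs_basis(x, np.asarray(t.knots))
        elif t.kind == "categorical":
            vals = df[t.name].to_numpy()
            block = np.column_stack([(vals == lv).astype(float) for lv in t.levels])
        else:
            raise ValueError(f"unknown term kind {t.kind!r}")
        blocks.append(block)
        idx = list(range(col, col + block.shape[1]))
        term_map[t.name] = idx
        if t.kind == "rcs":
            term_map[t.name + "_nonlinear"] = [idx[1]]
        names.extend(t.columns())
        col += block.shape[1]
        if spec.interaction is not None and t.name == spec.interaction[1]:
            steps_block = block
    if spec.interaction is not None:
        prs_name, steps_name = spec.interaction
        prs_term = spec.term(prs_name)
        prs_lin = df[prs_name].to_numpy(dtype=float) / prs_term.scale
        inter = steps_block * prs_lin[:, None]
        blocks.append(inter)
        term_map["interaction"] = list(range(col, col + inter.shape[1]))
        for c in spec.term(steps_name).columns():
            names.append(f"{prs_name}:{c}")
        col += inter.shape[1]
    X = np.hstack(blocks)
    return X, names, term_map


def default_model_spec(
    df: pd.DataFrame,
    include_baseline_bmi: bool = False,
    spline_vars: tuple = ("steps_current", "prs_residual", "baseline_age", "sbp"),
) -> ModelSpec:
    """The primary adjustment set on a counting-process frame.

    Steps (per 1000/day) and, by default, PRS, age and SBP enter as 3-knot
    splines (the latter three subject to the drop-to-linear rule); sex,
    cancer, CAD, alcohol and education are indicators; baseline steps are
    linear.  ``include_baseline_bmi`` adds baseline BMI (the sensitivity
    model kept apart from the primary fit because BMI and the PRS are
    collinear).
    """
    def cont(name, scale=1.0):
        x = df[name].to_numpy(dtype=float) / scale
        if name in spline_vars:
            return TermSpec(name, "rcs", knots=tuple(rcs_knots(x)), scale=scale)
        return TermSpec(name, "linear", scale=scale)

    ev = df[df["event"].astype(bool)]

    def level_ok(name, value) -> bool:
        # an indicator whose level has no events on one side is separated:
        # the partial likelihood is monotone in its coefficient
        hits = int((ev[name] == value).sum())
        return 0 < hits < len(ev)

    def binary_ok(name) -> bool:
        vals = ev[name].to_numpy(dtype=float)
        return vals.min() != vals.max()

    terms = [
        cont("steps_current", scale=1000.0),
        cont("prs_residual"),
        cont("baseline_age"),
    ]
    if level_ok("sex", "male"):
        terms.append(TermSpec("sex", "categorical", levels=("male",)))
    terms.append(TermSpec("baseline_steps", "linear", scale=1000.0))
    for name in ("cancer", "cad"):
        if binary_ok(name):
            terms.append(TermSpec(name, "linear"))
    terms.append(cont("sbp"))
    if binary_ok("alcohol"):
        terms.append(TermSpec("alcohol", "linear"))
    edu_levels = tuple(lv for lv in ("some_college", "no_college")
                       if level_ok("education", lv))
    if edu_levels:
        terms.append(TermSpec("education", "categorical", levels=edu_levels))
    if include_baseline_bmi:
        terms.append(TermSpec("baseline_bmi", "linear"))
    return ModelSpec(terms=tuple(terms),
                     interaction=("prs_residual", "steps_current"))


# --------------------------------------------------------------------------
# counting-process expansion
# --------------------------------------------------------------------------

def build_counting_process(
    cohort: pd.DataFrame,
    exposure: pd.DataFrame,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Expand the cohort to one row per person-month.

    Each row carries that calendar month's mean daily steps as
    ``steps_current`` over (start, stop] in years from the person's
    monitoring start.  Months failing the valid-days rule inherit the last
    observed monthly mean (counted in the ``gap_months`` audit column of the
    frame's attrs).  The final interval is truncated at the event or
    censoring time, with the event attached to it.
    """
    if covariate_cols is None:
        covariate_cols = [c for c in cohort.columns
                          if c not in ("person_id", "t0", "event", "time")]
    exp_by_person = dict(tuple(exposure.groupby("person_id")))
    rows = []
    gap_months = 0
    for rec in cohort.itertuples(index=False):
        pm = exp_by_person.get(rec.person_id)
        if pm is None or pm.empty:
            raise ValueError(f"person {rec.person_id} has no exposure months")
        pm = pm.sort_values("month_index")
        means = dict(zip(pm["month_index"], pm["mean_steps"]))
        t_starts = dict(zip(pm["month_index"], pm["t_start"]))
        t_stops = dict(zip(pm["month_index"], pm["t_stop"]))
        month_len = 1.0 / 12.0
        time = float(rec.time)
        if rec.event and time < min(t_starts.values()):
            raise ValueError(
                f"person {rec.person_id}: event at {time} precedes first exposure month"
            )
        m = 0
        last_mean = None
        start = 0.0
        max_m = max(means)
        while start < time - 1e-12:
            if m in means:
                last_mean = means[m]
                stop = t_stops[m]
            else:
                if last_mean is None:
                    # leading gap before the first valid month cannot occur:
                    # month_index 0 is the first valid month by construction
                    raise ValueError(f"person {rec.person_id}: no exposure at month 0")
                if m <= max_m:
                    gap_months += 1
                stop = start + month_len
            stop_eff = min(stop, time)
            if stop_eff > start:
                rows.append((rec.person_id, start, stop_eff, False, float(last_mean)))
            start = stop
            m += 1
        if rows and rec.event:
            pid, s, e, _, mn = rows[-1]
            rows[-1] = (pid, s, e, True, mn)
    out = pd.DataFrame(rows, columns=["person_id", "start", "stop", "event",
                                      "steps_current"])
    out = out.merge(cohort[["person_id"] + covariate_cols], on="person_id", how="left")
    out.attrs["gap_months"] = gap_months
    return out


# --------------------------------------------------------------------------
# Efron partial likelihood
# --------------------------------------------------------------------------

def _efron(X, start, stop, event, beta, want_hess=True):
    """Log partial likelihood, score and (optionally) Hessian, Efron ties."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ev = event.astype(bool)
    # tie groups: unique event times
    t_ev = stop[ev]
    t_unique, inverse = np.unique(t_ev, return_inverse=True)
    K = t_unique.shape[0]
    d = np.bincount(inverse, minlength=K).astype(float)
    Xe = X[ev]
    we = w[ev]
    xe_sum = np.zeros((K, p))
    s0e = np.bincount(inverse, weights=we, minlength=K)
    s1e = np.zeros((K, p))
    for j in range(p):
        xe_sum[:, j] = np.bincount(inverse, weights=Xe[:, j], minlength=K)
        s1e[:, j] = np.bincount(inverse, weights=we * Xe[:, j], minlength=K)

    lo = np.searchsorted(t_unique, start, side="right")
    hi = np.searchsorted(t_unique, stop, side="right")

    # S0/S1 via difference arrays over event-time index
    S0 = np.zeros(K + 1)
    np.add.at(S0, lo, w)
    np.add.at(S0, hi, -w)
    S0 = np.cumsum(S0)[:K]
    S1 = np.zeros((K + 1, p))
    np.add.at(S1, lo, w[:, None] * X)
    np.add.at(S1, hi, -(w[:, None] * X))
    S1 = np.cumsum(S1, axis=0)[:K]

    loglik = float(np.sum(xe_sum @ beta))
    grad = xe_sum.sum(axis=0)
    hess = np.zeros((p, p)) if want_hess else None

    if want_hess:
        # sweep over event times maintaining the risk-set S2
        order_in = np.argsort(lo, kind="stable")
        order_out = np.argsort(hi, kind="stable")
        lo_sorted = lo[order_in]
        hi_sorted = hi[order_out]
        ptr_in = ptr_out = 0
        S2 = np.zeros((p, p))
        s2e_k = np.zeros((p, p))
        for k in range(K):
            j = np.searchsorted(lo_sorted, k, side="right")
            if j > ptr_in:
                idx = order_in[ptr_in:j]
                Xi = X[idx]
                S2 += (w[idx][:, None] * Xi).T @ Xi
                ptr_in = j
            j = np.searchsorted(hi_sorted, k, side="right")
            if j > ptr_out:
                idx = order_out[ptr_out:j]
                Xi = X[idx]
                S2 -= (w[idx][:, None] * Xi).T @ Xi
                ptr_out = j
            dk = int(d[k])
            if dk > 1:
                tied = np.flatnonzero(inverse == k)
                Xt = Xe[tied]
                s2e_k = (we[tied][:, None] * Xt).T @ Xt
            if S0[k] <= 0:
                raise ValueError(f"empty risk set at event time {t_unique[k]}")
            for r in range(dk):
                f = r / dk
                den = S0[k] - f * s0e[k]
                num = S1[k] - f * s1e[k]
                loglik -= np.log(den)
                mu = num / den
                grad -= mu
                s2 = S2 - f * s2e_k if dk > 1 else S2
                hess -= s2 / den - np.outer(mu, mu)
    else:
        for k in range(K):
            if S0[k] <= 0:
                raise ValueError(f"empty risk set at event time {t_unique[k]}")
            dk = int(d[k])
            for r in range(dk):
                f = r / dk
                den = S0[k] - f * s0e[k]
                loglik -= np.log(den)
                grad -= (S1[k] - f * s1e[k]) / den
    return loglik, grad, hess


def efron_loglik(df: pd.DataFrame, X: np.ndarray, beta: np.ndarray) -> float:
    """Log partial likelihood at ``beta`` on counting-process rows."""
    ll, _, _ = _efron(
        np.asarray(X, dtype=float),
        df["start"].to_numpy(dtype=float),
        df["stop"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=bool),
        np.asarray(beta, dtype=float),
        want_hess=False,
    )
    return ll


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class ModelFit:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    names: list
    term_map: dict
    n_events: int
    spec: ModelSpec | None = None
    meta: dict = field(default_factory=dict)
    score: np.ndarray | None = None

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        se = self.se()
        z = self.beta / se
        return pd.DataFrame({
            "term": self.names,
            "coef": self.beta,
            "se": se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "hr": np.exp(self.beta),
        })


def _reference_profile(df: pd.DataFrame, spec: ModelSpec) -> dict:
    """Per-variable reference values: medians for continuous terms, the
    modal level for categoricals; used to build contrast design rows."""
    prof = {}
    for t in spec.terms:
        if t.kind == "categorical":
            prof[t.name] = df[t.name].mode().iloc[0]
        else:
            prof[t.name] = float(df[t.name].median())
    return prof


def fit_cox_tv(
    data: pd.DataFrame,
    spec: ModelSpec,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> ModelFit:
    """Maximise the Efron-corrected counting-process partial likelihood.

    Newton-Raphson with step halving; convergence requires the score
    vector's largest component below 1e-6.  Monotone likelihood (a
    coefficient running away) raises :class:`ConvergenceError`.
    """
    X, names, term_map = build_design(data, spec)
    if not data["event"].any():
        raise ValueError("no events in data")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        bad = [names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant covariate columns: {bad}")
    start = data["start"].to_numpy(dtype=float)
    stop = data["stop"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=bool)
    if np.any(start >= stop):
        raise ValueError("intervals must satisfy start < stop")

    p = X.shape[1]
    beta = np.zeros(p)
    ll, g, H = _efron(X, start, stop, event, beta)
    for it in range(max_iter):
        if np.abs(g).max() < 1e-8:
            break
        try:
            delta = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, g_new, H_new = _efron(X, start, stop, event, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-8:
                break
            step /= 2
        else:
            raise ConvergenceError("step halving failed to improve likelihood")
        beta, ll, g, H = cand, ll_new, g_new, H_new
        # a separated covariate plateaus at a huge coefficient with a
        # vanishing score; on this package's covariate scales any |beta|
        # this large is monotone likelihood, not a real estimate
        if np.abs(beta).max() > 15:
            raise ConvergenceError(
                "monotone likelihood: a coefficient diverged "
                f"(max |beta| = {np.abs(beta).max():.1f})"
            )
    else:
        if np.abs(g).max() > 1e-4:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations (max score "
                f"{np.abs(g).max():.2e})"
            )
    cov = np.linalg.inv(-H)
    meta = {"reference_profile": _reference_profile(data, spec)}
    if "steps_current" in data.columns:
        meta["steps_quantiles"] = np.quantile(
            data["steps_current"].to_numpy(dtype=float), np.linspace(0.01, 0.99, 99)
        )
    if "prs_residual" in data.columns and "person_id" in data.columns:
        per_person = data.groupby("person_id")["prs_residual"].first().to_numpy()
        meta["prs_quantiles"] = np.quantile(per_person, np.linspace(0.01, 0.99, 99))
    return ModelFit(
        beta=beta, cov=cov, loglik=ll, names=names, term_map=term_map,
        n_events=int(event.sum()), spec=spec, meta=meta, score=g,
    )


# --------------------------------------------------------------------------
# inference on blocks
# --------------------------------------------------------------------------

def wald_chunk_test(fit: ModelFit, term_block: str) -> dict:
    """Joint Wald test of a coefficient block: chi2 = b' V^-1 b, df = |block|."""
    if term_block not in fit.term_map:
        raise KeyError(f"unknown block {term_block!r}; have {sorted(fit.term_map)}")
    idx = fit.term_map[term_block]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular block covariance for {term_block!r}") from exc
    df = len(idx)
    return {"chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}


def drop_to_linear(
    data: pd.DataFrame, fit: ModelFit, variable: str, alpha: float = 0.05
) -> tuple[ModelFit, dict]:
    """Wald-test the nonlinear spline column of ``variable``; if it is not
    significant, refit with the variable linear.

    Returns the (possibly refitted) model and a report with the nonlinear
    p-value before the decision and the variable's overall p after.
    """
    block = variable + "_nonlinear"
    if block not in fit.term_map:
        raise KeyError(f"{variable} is not fitted as a spline")
    p_nonlin = wald_chunk_test(fit, block)["p"]
    is_linear = p_nonlin >= alpha
    if is_linear:
        fit = fit_cox_tv(data, fit.spec.with_linear(variable))
    p_overall = wald_chunk_test(fit, variable)["p"]
    report = {
        "variable": variable,
        "p_nonlinear": float(p_nonlin),
        "is_linear": bool(is_linear),
        "p_overall": float(p_overall),
    }
    return fit, report


def select_linearity(
    data: pd.DataFrame,
    spec: ModelSpec,
    candidates: tuple = ("prs_residual", "baseline_age", "sbp"),
    alpha: float = 0.05,
) -> tuple[ModelFit, list]:
    """Apply the drop-to-linear rule to each candidate spline variable.

    All candidates are tested on the full spline fit, then every
    non-significant curvature is dropped simultaneously and the model refit
    once.  Steps stay spline (the exposure of interest is allowed its
    curvature regardless).
    """
    fit = fit_cox_tv(data, spec)
    reports = []
    new_spec = spec
    for var in candidates:
        if var + "_nonlinear" not in fit.term_map:
            continue
        p_nonlin = wald_chunk_test(fit, var + "_nonlinear")["p"]
        linear = p_nonlin >= alpha
        reports.append({"variable": var, "p_nonlinear": float(p_nonlin),
                        "is_linear": bool(linear)})
        if linear:
            new_spec = new_spec.with_linear(var)
    if new_spec is not spec:
        fit = fit_cox_tv(data, new_spec)
    return fit, reports


# --------------------------------------------------------------------------
# proportional-hazards diagnostics
# --------------------------------------------------------------------------

def proportional_hazards_check(
    fit: ModelFit, data: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grambsch-Therneau tests of proportional hazards.

    Schoenfeld residuals at each event time are correlated with the event
    time (identity transform).  Returns (test table, residual table); the
    table has one df=1 row per coefficient plus a global df=p row.
    """
    X, _, _ = build_design(data, fit.spec)
    start = data["start"].to_numpy(dtype=float)
    stop = data["stop"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=bool)
    if not event.any():
        raise ValueError("no events")
    w = np.exp(X @ fit.beta)
    t_ev = stop[event]
    order = np.argsort(t_ev, kind="stable")
    t_sorted = t_ev[order]
    Xe = X[event][order]
    p = X.shape[1]
    resid = np.empty((t_sorted.shape[0], p))
    for i, t in enumerate(t_sorted):
        at_risk = (start < t) & (t <= stop)
        wr = w[at_risk]
        xbar = (wr[:, None] * X[at_risk]).sum(axis=0) / wr.sum()
        resid[i] = Xe[i] - xbar
    g = t_sorted
    gc = g - g.mean()
    d = float(len(g))
    denom = float(gc @ gc)
    rows = []
    if denom == 0:
        # a single event (or all events tied): no time variation to test
        for name in list(fit.names) + ["GLOBAL"]:
            rows.append({"term": name, "chi2": np.nan,
                         "df": 1 if name != "GLOBAL" else p, "p": np.nan})
    else:
        u = gc @ resid
        vu = fit.cov @ u
        global_chi2 = float(d / denom * (u @ vu))
        for j, name in enumerate(fit.names):
            chi2_j = d * vu[j] ** 2 / (fit.cov[j, j] * denom)
            rows.append({"term": name, "chi2": float(chi2_j), "df": 1,
                         "p": float(stats.chi2.sf(chi2_j, 1))})
        rows.append({"term": "GLOBAL", "chi2": global_chi2, "df": p,
                     "p": float(stats.chi2.sf(global_chi2, p))})
    table = pd.DataFrame(rows)
    resid_df = pd.DataFrame(resid, columns=fit.names)
    resid_df.insert(0, "time", t_sorted)
    return table, resid_df
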