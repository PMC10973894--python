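"""Counting-process Cox fitter: oracle equivalence, invariances, blocks,
tie handling, and proportional-hazards diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from steppath.cox import (
    ModelSpec, TermSpec, ModelFit, build_counting_process, build_design,
    fit_cox_tv, drop_to_linear, wald_chunk_test, proportional_hazards_check,
    efron_loglik, ConvergenceError, default_model_spec,
)
from conftest import tiny_counting_frame, linear_spec


def brute_force_log_pl(df, xcols, beta):
    """Independent partial likelihood: explicit product of risk-set ratios
    (no ties assumed; start-stop risk sets by direct predicate)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = df[xcols].to_numpy(dtype=float)
    ll = 0.0
    for i in df.index[df["event"]]:
        t = df.loc[i, "stop"]
        num = float(X[df.index.get_loc(i)] @ beta)
        at_risk = (df["start"].to_numpy() < t) & (t <= df["stop"].to_numpy())
        den = np.log(np.sum(np.exp(X[at_risk] @ beta)))
        ll += num - den
    return ll


class TestOracleEquivalence:
    def test_single_covariate_matches_brute_force(self):
        rng = np.random.default_rng(7)
        spec = ModelSpec(terms=(TermSpec("x0", "linear"),))
        compared = 0
        for rep in range(80):
            if compared >= 20:
                break
            df = tiny_counting_frame(rng, n_rows=int(rng.integers(4, 9)))
            res = optimize.minimize_scalar(
                lambda b: -brute_force_log_pl(df, ["x0"], b),
                bounds=(-30, 30), method="bounded",
                options={"xatol": 1e-10})
            if abs(res.x) > 8:
                continue  # flat/monotone likelihood: no interior optimum
            fit = fit_cox_tv(df, spec)
            assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)
            assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)
            compared += 1
        assert compared >= 20

    def test_two_covariates_match_nelder_mead(self):
        rng = np.random.default_rng(8)
        spec = ModelSpec(terms=(TermSpec("x0", "linear"), TermSpec("x1", "linear")))
        done = 0
        while done < 5:
            df = tiny_counting_frame(rng, n_rows=8, n_cov=2)
            try:
                fit = fit_cox_tv(df, spec)
            except ConvergenceError:
                continue
            res = optimize.minimize(
                lambda b: -brute_force_log_pl(df, ["x0", "x1"], b),
                x0=np.zeros(2), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            np.testing.assert_allclose(fit.beta, res.x, atol=1e-5)
            done += 1

    def test_loglik_evaluator_agrees_with_brute_force_at_fixed_beta(self):
        rng = np.random.default_rng(9)
        df = tiny_counting_frame(rng, n_rows=8, n_cov=2)
        X = df[["x0", "x1"]].to_numpy()
        for beta in ([0.0, 0.0], [0.5, -1.0], [-2.0, 0.3]):
            assert efron_loglik(df, X, beta) == pytest.approx(
                brute_force_log_pl(df, ["x0", "x1"], beta), abs=1e-10)


class TestInvariances:
    def test_replication_invariance(self):
        rng = np.random.default_rng(10)
        df = tiny_counting_frame(rng, n_rows=8)
        spec = ModelSpec(terms=(TermSpec("x0", "linear"),))
        fit1 = fit_cox_tv(df, spec)
        dup = pd.concat([df, df.assign(person_id=df["person_id"] + "_b")],
                        ignore_index=True)
        # jitter duplicate event times to stay in the no-ties regime is NOT
        # needed: Efron handles the exact ties introduced by duplication
        fit2 = fit_cox_tv(dup, spec)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-6)

    def test_scale_equivariance(self, linear_fit_large):
        cp = linear_fit_large["cp"]
        fit_k = linear_fit_large["fit"]  # steps scaled by 1000
        terms = (TermSpec("steps_current", "linear", scale=1.0),) + fit_k.spec.terms[1:]
        fit_raw = fit_cox_tv(cp, ModelSpec(terms=terms))
        assert fit_raw.beta[0] * 1000 == pytest.approx(fit_k.beta[0], rel=1e-6)

    def test_score_vanishes_and_cov_spd(self, linear_fit_large):
        fit = linear_fit_large["fit"]
        assert np.abs(fit.score).max() < 1e-6
        eig = np.linalg.eigvalsh(fit.cov)
        assert eig.min() > 0
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)


class TestTies:
    def test_efron_matches_lifelines_on_tied_data(self):
        from lifelines import CoxTimeVaryingFitter
        rng = np.random.default_rng(11)
        n = 60
        stop = rng.integers(1, 8, n).astype(float)  # heavy ties
        df = pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)],
            "start": 0.0, "stop": stop,
            "event": rng.random(n) < 0.6,
            "x0": rng.standard_normal(n),
        })
        fit = fit_cox_tv(df, ModelSpec(terms=(TermSpec("x0", "linear"),)))
        ctv = CoxTimeVaryingFitter()
        ctv.fit(df.rename(columns={"person_id": "pid"}), id_col="pid",
                start_col="start", stop_col="stop", event_col="event")
        assert fit.beta[0] == pytest.approx(ctv.params_["x0"], abs=1e-6)
        assert fit.se()[0] == pytest.approx(
            ctv.standard_errors_["x0"], abs=1e-6)


class TestCountingProcess:
    def _exposure(self, months, pid="A"):
        return pd.DataFrame({
            "person_id": pid,
            "month_index": range(len(months)),
            "mean_steps": months,
            "n_valid_days": 28,
            "t_start": [m / 12 for m in range(len(months))],
            "t_stop": [(m + 1) / 12 for m in range(len(months))],
        })

    def _cohort(self, time, event, pid="A"):
        return pd.DataFrame({
            "person_id": [pid], "event": [event], "time": [time],
            "prs_residual": [0.1],
        })

    def test_censored_three_months(self):
        cp = build_counting_process(self._cohort(3 / 12, False),
                                    self._exposure([8000, 9000, 7000]))
        assert len(cp) == 3
        assert not cp["event"].any()
        np.testing.assert_allclose(cp["steps_current"], [8000, 9000, 7000])
        np.testing.assert_allclose(cp["stop"], [1 / 12, 2 / 12, 3 / 12])

    def test_event_mid_month_truncates(self):
        months = [8000.0] * 12
        cp = build_counting_process(self._cohort(0.7, True), self._exposure(months))
        last = cp.iloc[-1]
        assert last["stop"] == pytest.approx(0.7)
        assert last["event"]
        assert cp["event"].sum() == 1
        # interval containing 0.7 years is month 9 (index 8)
        assert len(cp) == 9

    def test_single_month_starts_at_zero(self):
        cp = build_counting_process(self._cohort(1 / 12, False),
                                    self._exposure([5000]))
        assert len(cp) == 1
        assert cp.iloc[0]["start"] == 0.0

    def test_gap_months_carry_forward_with_audit(self):
        exp = self._exposure([8000, 9000, 7000])
        exp = exp[exp["month_index"] != 1]  # month 1 failed the 15-day rule
        cp = build_counting_process(self._cohort(3 / 12, False), exp)
        assert len(cp) == 3
        assert cp.iloc[1]["steps_current"] == 8000  # carried forward
        assert cp.attrs["gap_months"] == 1

    def test_event_before_first_month_is_error(self):
        exp = self._exposure([8000])
        exp["t_start"] += 1.0
        exp["t_stop"] += 1.0
        with pytest.raises(ValueError, match="precedes"):
            build_counting_process(self._cohort(0.5, True), exp)

    def test_intervals_partition_followup(self, linear_fit_large):
        cp = linear_fit_large["cp"]
        g = cp.sort_values(["person_id", "start"]).groupby("person_id")
        assert (g.apply(lambda d: np.allclose(d["start"].iloc[1:],
                                              d["stop"].iloc[:-1]),
                        include_groups=False)).all()
        assert (cp["start"] < cp["stop"]).all()
        assert (cp.groupby("person_id")["event"].sum() <= 1).all()


class TestChunkAndLinearity:
    def test_printed_chi2_df2_pairing(self):
        # chi-square survival: 1.98 on 2 df
        assert stats.chi2.sf(1.98, 2) == pytest.approx(0.372, abs=5e-4)

    def _toy_fit(self, beta, cov, names=None):
        p = len(beta)
        names = names or [f"b{i}" for i in range(p)]
        return ModelFit(beta=np.asarray(beta, float), cov=np.asarray(cov, float),
                        loglik=0.0, names=names,
                        term_map={n: [i] for i, n in enumerate(names)}
                        | {"block": list(range(p))}, n_events=10)

    def test_zero_coefficients_give_p_one(self):
        fit = self._toy_fit([0.0, 0.0], np.eye(2))
        out = wald_chunk_test(fit, "block")
        assert out["chi2"] == 0.0 and out["p"] == 1.0

    def test_one_df_block_equals_squared_z(self):
        fit = self._toy_fit([0.4], [[0.04]])
        out = wald_chunk_test(fit, "b0")
        z = 0.4 / 0.2
        assert out["chi2"] == pytest.approx(z**2)
        assert out["p"] == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_interaction_block_is_two_df(self, spline_fit_large):
        out = wald_chunk_test(spline_fit_large["fit"], "interaction")
        assert out["df"] == 2

    def test_drop_to_linear_single_variable(self, linear_fit_large):
        cp = linear_fit_large["cp"]
        spec = default_model_spec(cp, spline_vars=("steps_current", "prs_residual"))
        fit = fit_cox_tv(cp, spec)
        new_fit, report = drop_to_linear(cp, fit, "prs_residual")
        assert report["variable"] == "prs_residual"
        assert 0 <= report["p_nonlinear"] <= 1
        if report["is_linear"]:
            assert "prs_residual_nonlinear" not in new_fit.term_map
        else:
            assert "prs_residual_nonlinear" in new_fit.term_map


class TestErrors:
    def test_no_events_rejected(self):
        df = tiny_counting_frame(np.random.default_rng(1), 5)
        df["event"] = False
        with pytest.raises(ValueError, match="event"):
            fit_cox_tv(df, ModelSpec(terms=(TermSpec("x0", "linear"),)))

    def test_constant_column_rejected(self):
        df = tiny_counting_frame(np.random.default_rng(2), 6)
        df["x0"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox_tv(df, ModelSpec(terms=(TermSpec("x0", "linear"),)))

    def test_monotone_likelihood_detected(self):
        # perfectly separating covariate: events all have x=1, censored x=0
        df = pd.DataFrame({
            "person_id": list("abcdef"),
            "start": 0.0,
            "stop": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [True, True, True, False, False, False],
            "x0": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        })
        with pytest.raises(ConvergenceError):
            fit_cox_tv(df, ModelSpec(terms=(TermSpec("x0", "linear"),)))


class TestProportionalHazards:
    def test_single_event_residual_table(self):
        df = pd.DataFrame({
            "person_id": list("abcd"), "start": 0.0,
            "stop": [1.0, 2.0, 3.0, 4.0],
            "event": [False, True, False, False],
            # the event's covariate sits inside the risk set's range, so the
            # partial likelihood has an interior maximum
            "x0": [0.1, 0.3, 0.5, -0.2],
        })
        fit = fit_cox_tv(df, ModelSpec(terms=(TermSpec("x0", "linear"),)))
        table, resid = proportional_hazards_check(fit, df)
        assert len(resid) == 1
        assert set(table["term"]) == {"x0", "GLOBAL"}

    @staticmethod
    def _simulate_ph(rng, n, time_varying=False):
        """Single-interval survival; optionally an effect that grows in time
        (hazard ~ exp(beta(t) x) with beta(t) = 2.5 t), via fine intervals."""
        x = rng.standard_normal(n)
        if not time_varying:
            t = rng.exponential(1.0, n) / np.exp(0.8 * x)
            cens = rng.uniform(0.5, 3.0, n)
            df = pd.DataFrame({
                "person_id": [f"p{i}" for i in range(n)],
                "start": 0.0, "stop": np.minimum(t, cens),
                "event": t <= cens, "x0": x,
            })
            return df
        rows = []
        dt = 0.1
        for i in range(n):
            t = 0.0
            while t < 3.0:
                lam = 0.25 * np.exp(2.5 * max(t, 0.0) * x[i])
                u = rng.exponential(1.0)
                if u < lam * dt:
                    frac = u / (lam * dt)
                    rows.append((f"p{i}", t, t + frac * dt, True, x[i]))
                    break
                rows.append((f"p{i}", t, t + dt, False, x[i]))
                t += dt
        return pd.DataFrame(rows, columns=["person_id", "start", "stop",
                                           "event", "x0"])

    def test_nominal_level_under_proportional_truth(self):
        rng = np.random.default_rng(123)
        spec = ModelSpec(terms=(TermSpec("x0", "linear"),))
        rejections = 0
        reps = 40
        for _ in range(reps):
            df = self._simulate_ph(rng, 250)
            fit = fit_cox_tv(df, spec)
            table, _ = proportional_hazards_check(fit, df)
            if table.loc[table["term"] == "GLOBAL", "p"].iloc[0] < 0.05:
                rejections += 1
        # Binomial(40, 0.05): >= 8 rejections has probability < 3e-4
        assert rejections <= 7

    def test_power_against_time_increasing_effect(self):
        rng = np.random.default_rng(321)
        spec = ModelSpec(terms=(TermSpec("x0", "linear"),))
        rejections = 0
        reps = 20
        for _ in range(reps):
            df = self._simulate_ph(rng, 150, time_varying=True)
            fit = fit_cox_tv(df, spec)
            table, _ = proportional_hazards_check(fit, df)
            if table.loc[table["term"] == "x0", "p"].iloc[0] < 0.05:
                rejections += 1
        assert rejections >= 0.8 * reps
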