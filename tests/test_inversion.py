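"""HR-curve construction, dense-spline inversion, and CI propagation."""

import numpy as np
import pandas as pd
import pytest

from steppath.cox import ModelFit, ModelSpec, TermSpec
from steppath.inversion import (
    HRCurve, hr_curve, fit_dense_spline, invert_to_unit_hr,
    ci_band_inversion, steps_vs_prs_profile,
)


def synthetic_fit(beta_steps=-1e-4, beta_prs=0.5, beta_bmi=0.0, cov_scale=1e-3,
                  prs_spread=3.0):
    """Hand-built linear ModelFit with known coefficients (steps per 1 step
    here, so the closed-form crossing is easy to state)."""
    terms = [
        TermSpec("steps_current", "linear", scale=1.0),
        TermSpec("prs_residual", "linear"),
    ]
    beta = [beta_steps, beta_prs]
    if beta_bmi:
        terms.append(TermSpec("baseline_bmi", "linear"))
        beta.append(beta_bmi)
    p = len(beta)
    prs_q = np.linspace(-prs_spread / 2, prs_spread / 2, 99)
    return ModelFit(
        beta=np.asarray(beta, float), cov=cov_scale * np.eye(p),
        loglik=0.0, names=[t.name for t in terms],
        term_map={t.name: [i] for i, t in enumerate(terms)},
        n_events=100,
        spec=ModelSpec(terms=tuple(terms)),
        meta={
            "reference_profile": {"steps_current": 8000.0, "prs_residual": 0.0,
                                  "baseline_bmi": 25.0},
            "steps_quantiles": np.linspace(3000, 15000, 99),
            "prs_quantiles": prs_q,
        },
    )


class TestHRCurve:
    def test_reference_self_contrast_is_zero_with_zero_variance(self):
        fit = synthetic_fit()
        grid = np.linspace(3000.0, 13000.0, 501)  # contains 8000 exactly
        curve = hr_curve(fit, 50, step_grid=grid, reference=(50, 8000.0))
        i = int(np.flatnonzero(grid == 8000.0)[0])
        assert curve.log_hr[i] == pytest.approx(0.0, abs=1e-12)
        var = ((curve.upper - curve.log_hr) / 1.96) ** 2
        assert var[i] == pytest.approx(0.0, abs=1e-15)

    def test_no_interaction_curves_are_vertical_shifts(self):
        fit = synthetic_fit()
        c25 = hr_curve(fit, 25)
        c75 = hr_curve(fit, 75)
        diff = c75.log_hr - c25.log_hr
        np.testing.assert_allclose(diff, diff[0], atol=1e-12)

    def test_delta_method_variance_matches_parametric_bootstrap(self):
        rng = np.random.default_rng(4)
        fit = synthetic_fit(cov_scale=0.0)
        # non-diagonal covariance to make the delta method non-trivial
        A = rng.normal(size=(2, 2))
        fit.cov = 1e-6 * (A @ A.T + 2 * np.eye(2))
        curve = hr_curve(fit, 75, reference=(50, 8000.0))
        draws = rng.multivariate_normal(fit.beta, fit.cov, size=2000)
        for s in (4000.0, 8000.0, 12000.0):
            i = np.argmin(np.abs(curve.step_grid - s))
            x = curve.step_grid[i]
            prs75 = np.interp(75, np.linspace(1, 99, 99), fit.meta["prs_quantiles"])
            d = np.array([x - 8000.0, prs75 - 0.0])
            boot = draws @ d
            delta_sd = (curve.upper[i] - curve.log_hr[i]) / 1.96
            assert delta_sd == pytest.approx(boot.std(), rel=0.05)


class TestDenseSpline:
    def test_reproduces_line_and_interpolates(self):
        x = np.linspace(0, 10000, 500)
        y = 0.3 - 1e-4 * x
        sp = fit_dense_spline(x, y)
        dense = np.linspace(0, 10000, 4001)
        np.testing.assert_allclose(sp(dense), 0.3 - 1e-4 * dense, atol=1e-8)
        np.testing.assert_allclose(sp(x), y, atol=1e-12)

    def test_sine_midpoint_accuracy(self):
        x = np.arange(0, 10000.0 + 1, 100.0)
        y = np.sin(x / 2000.0)
        sp = fit_dense_spline(x, y)
        mid = x[:-1] + 50.0
        assert np.max(np.abs(sp(mid) - np.sin(mid / 2000.0))) < 1e-4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="grid points"):
            fit_dense_spline(np.linspace(0, 1, 50), np.zeros(50))


class TestInversion:
    def test_closed_form_linear_root(self):
        x = np.linspace(0, 10000, 500)
        sp = fit_dense_spline(x, 0.30 - 1e-4 * x)
        res = invert_to_unit_hr(sp, (0, 10000))
        assert res.steps == pytest.approx(3000.0, abs=1.0)
        assert not res.multiple

    def test_entirely_negative_curve_absent_with_sign(self):
        x = np.linspace(0, 10000, 500)
        sp = fit_dense_spline(x, -0.2 - 1e-5 * x)
        res = invert_to_unit_hr(sp, (0, 10000))
        assert res.steps is None and res.sign == -1

    def test_multiple_crossings_flagged_smallest_returned(self):
        x = np.linspace(0, 10000, 1000)
        y = np.sin(x / 1000.0) * 0.1 + 0.05
        sp = fit_dense_spline(x, y)
        res = invert_to_unit_hr(sp, (0, 10000))
        assert res.multiple
        first = res.steps
        assert sp(first) == pytest.approx(0.0, abs=1e-3)
        assert first < 5000


class TestBandInversion:
    def _curve(self, half_width):
        x = np.linspace(0, 10000, 500)
        y = 0.30 - 1e-4 * x
        return HRCurve(prs_percentile=50, step_grid=x, log_hr=y,
                       lower=y - half_width, upper=y + half_width)

    def test_symmetric_linear_bands(self):
        tgt = ci_band_inversion(self._curve(0.1))
        assert tgt.steps_at_unit_hr == pytest.approx(3000, abs=1)
        assert tgt.ci_low == pytest.approx(2000, abs=1)
        assert tgt.ci_high == pytest.approx(4000, abs=1)
        assert tgt.flags == ()

    def test_zero_width_band_collapses(self):
        tgt = ci_band_inversion(self._curve(0.0))
        assert tgt.ci_low == pytest.approx(tgt.steps_at_unit_hr, abs=1)
        assert tgt.ci_high == pytest.approx(tgt.steps_at_unit_hr, abs=1)

    def test_band_above_zero_unattainable(self):
        x = np.linspace(0, 10000, 500)
        y = 0.5 + 0.0 * x + 1e-6 * x  # strictly positive
        curve = HRCurve(prs_percentile=50, step_grid=x, log_hr=y,
                        lower=y - 0.05, upper=y + 0.05)
        tgt = ci_band_inversion(curve)
        assert tgt.steps_at_unit_hr is None
        assert "unattainable_in_range" in tgt.flags

    def test_ordering_when_all_exist(self):
        tgt = ci_band_inversion(self._curve(0.07))
        assert tgt.ci_low < tgt.steps_at_unit_hr < tgt.ci_high


class TestRoundTripAndReference:
    def test_round_trip_log_hr_at_target(self):
        fit = synthetic_fit()
        curve = hr_curve(fit, 75)
        sp = fit_dense_spline(curve.step_grid, curve.log_hr)
        res = invert_to_unit_hr(sp, (curve.step_grid[0], curve.step_grid[-1]))
        assert abs(sp(res.steps)) < 1e-3

    def test_reference_invariance_of_targets(self):
        """Re-deriving targets from a 25th-percentile reference and
        re-indexing reproduces the 50th-referenced targets."""
        fit = synthetic_fit()
        t50 = steps_vs_prs_profile(fit, [10, 30, 70, 90], reference=(50, 8000.0))
        # reference at the 25th percentile, at the step count that made the
        # 25th-percentile curve cross zero under the 50th reference
        t25_under_50 = steps_vs_prs_profile(fit, [25], reference=(50, 8000.0))
        s25 = t25_under_50["steps_at_unit_hr"].iloc[0]
        t_re = steps_vs_prs_profile(fit, [10, 30, 70, 90], reference=(25, s25))
        np.testing.assert_allclose(
            t_re["steps_at_unit_hr"], t50["steps_at_unit_hr"], atol=2.0)


class TestProfile:
    def test_positive_prs_effect_profile_increasing(self, spline_fit_large):
        from scipy.stats import spearmanr
        fit = spline_fit_large["fit"]
        prof = steps_vs_prs_profile(fit, list(range(5, 100, 10)))
        vals = prof["steps_at_unit_hr"].to_numpy(dtype=float)
        assert np.isfinite(vals).all()
        rho = spearmanr(prof["prs_percentile"], vals).statistic
        assert rho > 0.95

    def test_bmi_strata_shift_targets_monotonically(self):
        fit = synthetic_fit(beta_bmi=0.05)
        prof = steps_vs_prs_profile(fit, [25, 50, 75], bmi_strata=[22, 24, 26, 28],
                                    reference=(50, 8000.0))
        for pct in (25, 50, 75):
            sub = prof[prof["prs_percentile"] == pct].sort_values(
                "baseline_bmi_stratum")
            vals = sub["steps_at_unit_hr"].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            assert (np.diff(vals[ok]) > 0).all()

    def test_strata_require_bmi_term(self):
        fit = synthetic_fit()  # no baseline_bmi term
        with pytest.raises(ValueError, match="bmi_adjusted"):
            steps_vs_prs_profile(fit, [50], bmi_strata=[22])
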