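"""Inversion of the fitted hazard-ratio surface to step-count targets.

The fitted model gives, for each polygenic-score percentile, a hazard
ratio curve over mean daily steps indexed to a reference (by default the
50th percentile at the cohort-median step count).  A dense cubic spline
is fitted to the curve and inverted by bracketed root finding to the
step count where HR = 1.00; the 95% CI is obtained by inverting the
pointwise confidence-band edges the same way.  Stratification by
baseline BMI evaluates the BMI-adjusted model at fixed BMI values while
keeping the reference fixed, so strata shift the whole curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .cox import ModelFit, build_design


@dataclass
class HRCurve:
    """Pointwise log hazard ratio over a step grid at one PRS percentile."""

    prs_percentile: float
    step_grid: np.ndarray
    log_hr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    reference: dict = field(default_factory=dict)


@dataclass
class StepTarget:
    prs_percentile: float
    steps_at_unit_hr: float | None
    ci_low: float | None
    ci_high: float | None
    baseline_bmi_stratum: float | None = None
    flags: tuple = ()


def _percentile_to_prs(fit: ModelFit, percentile: float) -> float:
    q = fit.meta.get("prs_quantiles")
    if q is None:
        raise ValueError("fit has no PRS quantile map in meta")
    return float(np.interp(percentile, np.linspace(1, 99, 99), q))


def _design_rows(fit: ModelFit, values: dict, n: int) -> np.ndarray:
    """Design rows from a profile dict (scalars broadcast to n rows)."""
    cols = {}
    for t in fit.spec.terms:
        v = values.get(t.name, fit.meta["reference_profile"][t.name])
        cols[t.name] = np.broadcast_to(np.asarray(v), (n,)) if not np.isscalar(v) \
            else np.full(n, v)
    df = pd.DataFrame(cols)
    X, _, _ = build_design(df, fit.spec)
    return X


def hr_curve(
    fit: ModelFit,
    prs_percentile: float,
    step_grid: np.ndarray | None = None,
    reference: tuple | None = None,
    overrides: dict | None = None,
    n_grid: int = 500,
) -> HRCurve:
    """Log-HR over a step grid at one PRS percentile, with a delta-method
    pointwise 95% band.

    ``reference`` is (reference percentile, reference step count); defaults
    to (50, cohort-median steps).  All covariates other than steps and PRS
    sit at the cohort reference profile so they cancel in the contrast —
    except entries in ``overrides`` (e.g. a fixed baseline BMI), which apply
    to the curve side only and therefore shift it.
    """
    sq = fit.meta["steps_quantiles"]
    if step_grid is None:
        step_grid = np.linspace(sq[0], sq[-1], n_grid)
    step_grid = np.asarray(step_grid, dtype=float)
    if step_grid[0] < sq[0] - 1 or step_grid[-1] > sq[-1] + 1:
        import warnings
        warnings.warn(
            "step grid extends beyond the observed 1st-99th percentile range; "
            "the spline is linear there by construction", stacklevel=2)
    ref_pct, ref_steps = reference if reference is not None else (50.0, None)
    if ref_steps is None:
        ref_steps = float(np.median(sq))  # median of person-month means
    prs_val = _percentile_to_prs(fit, prs_percentile)
    ref_prs = _percentile_to_prs(fit, ref_pct)

    n = step_grid.shape[0]
    grid_vals = {"steps_current": step_grid, "prs_residual": prs_val}
    if overrides:
        grid_vals.update(overrides)
    Xg = _design_rows(fit, grid_vals, n)
    Xr = _design_rows(fit, {"steps_current": ref_steps, "prs_residual": ref_prs}, 1)
    D = Xg - Xr
    log_hr = D @ fit.beta
    var = np.einsum("ij,jk,ik->i", D, fit.cov, D)
    half = 1.96 * np.sqrt(np.maximum(var, 0.0))
    return HRCurve(
        prs_percentile=float(prs_percentile),
        step_grid=step_grid,
        log_hr=log_hr,
        lower=log_hr - half,
        upper=log_hr + half,
        reference={"percentile": ref_pct, "steps": ref_steps,
                   "overrides": dict(overrides or {})},
    )


def fit_dense_spline(x: np.ndarray, y: np.ndarray, min_knots: int = 100):
    """Interpolating cubic spline through (x, y) with knots at the grid.

    Requires at least ``min_knots`` grid points; reproduces the input
    values exactly at the grid and extrapolates with the boundary cubics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < min_knots:
        raise ValueError(f"need >= {min_knots} grid points, got {x.shape[0]}")
    return CubicSpline(x, y)


@dataclass
class InversionResult:
    steps: float | None
    multiple: bool = False
    sign: int = 0   # sign of the curve when no crossing exists


def invert_to_unit_hr(
    spline, bounds: tuple, tol: float = 0.5, scan_step: float = 1.0
) -> InversionResult:
    """Smallest root of log-HR(steps) = 0 in ``bounds``.

    Scans at 1-step resolution for sign changes, then solves each bracket
    with Brent's method to ``tol`` steps.  Multiple crossings are flagged
    and the smallest returned; no crossing returns the curve's sign instead.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    xs = np.arange(lo, hi + scan_step, scan_step)
    ys = spline(xs)
    sign = np.sign(ys)
    roots = []
    exact = np.flatnonzero(sign == 0)
    for i in exact:
        roots.append(float(xs[i]))
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    for i in changes:
        roots.append(float(brentq(spline, xs[i], xs[i + 1], xtol=tol)))
    if not roots:
        return InversionResult(steps=None, sign=int(np.sign(ys.mean())))
    roots = sorted(roots)
    return InversionResult(steps=roots[0], multiple=len(roots) > 1)


def ci_band_inversion(curve: HRCurve, min_knots: int = 100) -> StepTarget:
    """Invert the point curve and both band edges to a StepTarget.

    For the usual decreasing curve the lower log-HR band crosses zero at a
    smaller step count (the optimistic bound) and the upper band at a
    larger one.  Band edges with no crossing yield a one-sided or absent
    interval, flagged accordingly.
    """
    bounds = (curve.step_grid[0], curve.step_grid[-1])
    flags = []
    point = invert_to_unit_hr(fit_dense_spline(curve.step_grid, curve.log_hr,
                                               min_knots), bounds)
    if point.multiple:
        flags.append("multiple_crossings")
    res_lo = invert_to_unit_hr(fit_dense_spline(curve.step_grid, curve.lower,
                                                min_knots), bounds)
    res_hi = invert_to_unit_hr(fit_dense_spline(curve.step_grid, curve.upper,
                                                min_knots), bounds)
    if point.steps is None:
        flags.append("no_crossing" if res_lo.steps is None and res_hi.steps is None
                     else "point_no_crossing")
        if res_lo.steps is None and res_hi.steps is None:
            flags.append("unattainable_in_range")
    if point.steps is not None and (res_lo.steps is None or res_hi.steps is None):
        flags.append("one_sided_interval")
    lo_val, hi_val = res_lo.steps, res_hi.steps
    if lo_val is not None and hi_val is not None and lo_val > hi_val:
        lo_val, hi_val = hi_val, lo_val  # increasing curve: bands swap roles
    return StepTarget(
        prs_percentile=curve.prs_percentile,
        steps_at_unit_hr=point.steps,
        ci_low=lo_val,
        ci_high=hi_val,
        flags=tuple(flags),
    )


def steps_vs_prs_profile(
    fit: ModelFit,
    percentiles,
    bmi_strata=None,
    reference: tuple | None = None,
    n_grid: int = 500,
) -> pd.DataFrame:
    """Step-count targets at HR = 1.00 across PRS percentiles (and,
    optionally, fixed baseline-BMI strata of the BMI-adjusted model)."""
    strata = list(bmi_strata) if bmi_strata is not None else [None]
    rows = []
    for stratum in strata:
        overrides = {"baseline_bmi": stratum} if stratum is not None else None
        if stratum is not None and "baseline_bmi" not in [t.name for t in fit.spec.terms]:
            raise ValueError("baseline-BMI strata need the bmi_adjusted model")
        for pct in percentiles:
            curve = hr_curve(fit, pct, reference=reference, overrides=overrides,
                             n_grid=n_grid)
            target = ci_band_inversion(curve)
            target.baseline_bmi_stratum = stratum
            rows.append({
                "prs_percentile": pct,
                "baseline_bmi_stratum": stratum,
                "steps_at_unit_hr": target.steps_at_unit_hr,
                "ci_low": target.ci_low,
                "ci_high": target.ci_high,
                "flags": ",".join(target.flags),
            })
    return pd.DataFrame(rows)
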