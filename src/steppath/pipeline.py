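"""End-to-end orchestration: simulate -> curate -> score -> fit -> invert
-> incidence, with a run manifest, attrition table and plain-text summary.

Each stage is a thin call into the library; the pipeline exists so a
whole analysis is reproducible from one config and one seed.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__
from .synthetic import SimulationConfig, generate_cohort
from .curation import CurationConfig, filter_valid_days, monthly_means, assemble_cohort
from .genetics import build_score_set, incremental_nagelkerke
from .cox import (
    ModelFit, ModelSpec, TermSpec, build_counting_process, default_model_spec,
    fit_cox_tv, select_linearity, wald_chunk_test,
)
from .imputation import pmm_impute, pool_fits
from .inversion import steps_vs_prs_profile, hr_curve, _percentile_to_prs, _design_rows
from .incidence import breslow_baseline, incidence_table


@dataclass
class PipelineConfig:
    outdir: str = "steppath_run"
    # either simulate ...
    simulate: SimulationConfig | None = None
    # ... or point at same-schema CSVs
    steps_csv: str | None = None
    bmi_csv: str | None = None
    genetics_csv: str | None = None
    covariates_csv: str | None = None
    curation: CurationConfig = field(default_factory=CurationConfig)
    model: str = "primary"            # 'primary' | 'bmi_adjusted'
    m_imputations: int = 10
    k_donors: int = 5
    seed: int = 7
    percentiles: tuple = tuple(range(5, 100, 5))
    bmi_strata: tuple = (22, 24, 26, 28)
    incidence_percentiles: tuple = (25, 50, 75)
    step_levels: tuple = (7500, 10000, 12500)
    years: tuple = (1.0, 3.0, 5.0)
    reference_percentile: float = 50.0

    def validate(self) -> None:
        if self.model not in ("primary", "bmi_adjusted"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.m_imputations < 1:
            raise ValueError("m_imputations must be >= 1")
        self.curation.validate()
        if self.simulate is None and not (self.steps_csv and self.bmi_csv):
            raise ValueError("either a simulation config or input CSVs are required")


# --------------------------------------------------------------------------
# model fitting used by both the pipeline and the CLI `fit` verb
# --------------------------------------------------------------------------

def fit_analysis_model(
    cohort: pd.DataFrame,
    exposure: pd.DataFrame,
    model: str = "primary",
    m: int = 10,
    seed: int = 0,
    k_donors: int = 5,
) -> tuple[ModelFit, dict]:
    """Impute, select spline-vs-linear terms, fit all completed datasets,
    and pool by Rubin's rules.

    Drop-to-linear decisions are made once on the first completed dataset
    so the pooled fits share one term map.
    """
    include_bmi = model == "bmi_adjusted"
    completed = pmm_impute(cohort, m=m, seed=seed, k_donors=k_donors)
    # intervals depend only on exposure and event times, so the expansion is
    # built once and person-level covariates are re-merged per imputation
    skeleton = build_counting_process(cohort, exposure, covariate_cols=[])
    cov_cols = [c for c in cohort.columns if c not in ("person_id", "t0", "event", "time")]

    def expand(c):
        return skeleton.merge(c[["person_id"] + cov_cols], on="person_id", how="left")

    cp0 = expand(completed[0])
    spec0 = default_model_spec(cp0, include_baseline_bmi=include_bmi)
    fit0, linearity = select_linearity(cp0, spec0)
    spec = fit0.spec
    fits = [fit0]
    for c in completed[1:]:
        fits.append(fit_cox_tv(expand(c), spec))
    pooled = pool_fits(fits)
    report = {
        "linearity": linearity,
        "interaction": wald_chunk_test(pooled, "interaction"),
        "m": m,
        "model": model,
    }
    return pooled, report


def hr_contrast(fit: ModelFit, variable: str, upper_pct=75, lower_pct=25) -> dict:
    """HR comparing the variable's 75th vs 25th cohort percentile, other
    covariates at the reference profile (PRS on the percentile scale,
    steps on the person-month distribution)."""
    if variable == "prs_residual":
        hi = {"prs_residual": _percentile_to_prs(fit, upper_pct)}
        lo = {"prs_residual": _percentile_to_prs(fit, lower_pct)}
    elif variable == "steps_current":
        q = fit.meta["steps_quantiles"]
        grid = np.linspace(1, 99, 99)
        hi = {"steps_current": float(np.interp(upper_pct, grid, q))}
        lo = {"steps_current": float(np.interp(lower_pct, grid, q))}
    else:
        raise ValueError(f"no percentile contrast defined for {variable!r}")
    d = (_design_rows(fit, hi, 1) - _design_rows(fit, lo, 1))[0]
    est = float(d @ fit.beta)
    se = float(np.sqrt(d @ fit.cov @ d))
    z = est / se
    return {
        "hr": float(np.exp(est)),
        "ci_low": float(np.exp(est - 1.96 * se)),
        "ci_high": float(np.exp(est + 1.96 * se)),
        "p": float(2 * stats.norm.sf(abs(z))),
    }


# --------------------------------------------------------------------------
# fit (de)serialization for the CLI
# --------------------------------------------------------------------------

def fit_to_dict(fit: ModelFit) -> dict:
    spec = None
    if fit.spec is not None:
        spec = {
            "terms": [asdict(t) for t in fit.spec.terms],
            "interaction": list(fit.spec.interaction) if fit.spec.interaction else None,
        }
    meta = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in fit.meta.items()}
    return {
        "beta": fit.beta.tolist(),
        "cov": fit.cov.tolist(),
        "loglik": fit.loglik,
        "names": list(fit.names),
        "term_map": {k: list(v) for k, v in fit.term_map.items()},
        "n_events": fit.n_events,
        "spec": spec,
        "meta": meta,
    }


def fit_from_dict(d: dict) -> ModelFit:
    spec = None
    if d.get("spec") is not None:
        terms = tuple(
            TermSpec(
                name=t["name"], kind=t["kind"],
                knots=tuple(t["knots"]) if t.get("knots") else None,
                levels=tuple(t["levels"]) if t.get("levels") else None,
                scale=t.get("scale", 1.0),
            )
            for t in d["spec"]["terms"]
        )
        inter = d["spec"]["interaction"]
        spec = ModelSpec(terms=terms, interaction=tuple(inter) if inter else None)
    meta = {
        k: (np.asarray(v, dtype=float)
            if k in ("steps_quantiles", "prs_quantiles", "df",
                     "between_diag", "within_diag") else v)
        for k, v in d["meta"].items()
    }
    return ModelFit(
        beta=np.asarray(d["beta"], dtype=float),
        cov=np.asarray(d["cov"], dtype=float),
        loglik=float(d["loglik"]),
        names=list(d["names"]),
        term_map={k: list(v) for k, v in d["term_map"].items()},
        n_events=int(d["n_events"]),
        spec=spec,
        meta=meta,
    )


# --------------------------------------------------------------------------
# descriptive table
# --------------------------------------------------------------------------

def describe_cohort(
    cohort: pd.DataFrame, suppress_below: int = 20
) -> pd.DataFrame:
    """Characteristics across PRS quartiles: median (IQR) for continuous
    variables, n (%) for categoricals, with small-cell suppression.

    Quartiles are rank-based on ``percentile`` (or ``prs_residual``);
    counts below ``suppress_below`` are rendered as '<k'.
    """
    key = "percentile" if "percentile" in cohort.columns else "prs_residual"
    ranks = stats.rankdata(cohort[key], method="ordinal")
    quart = np.ceil(ranks * 4 / len(cohort)).astype(int)
    cont = [c for c in ("baseline_age", "baseline_bmi", "baseline_steps",
                        "sbp", "time") if c in cohort.columns]
    cat = [c for c in ("sex", "cancer", "cad", "alcohol", "education",
                       "smoking", "event") if c in cohort.columns]
    rows = []
    for q in (1, 2, 3, 4):
        sub = cohort[quart == q]
        row = {"quartile": q, "n": len(sub)}
        for c in cont:
            med = sub[c].median()
            lo, hi = sub[c].quantile([0.25, 0.75])
            row[c] = f"{med:.1f} ({lo:.1f}-{hi:.1f})"
        for c in cat:
            vals = sub[c].dropna()
            counts = vals.value_counts()
            parts = []
            for level, cnt in counts.items():
                shown = f"<{suppress_below}" if cnt < suppress_below else str(cnt)
                parts.append(f"{level}: {shown} ({100 * cnt / max(len(vals), 1):.0f}%)")
            row[c] = "; ".join(parts)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# the full run
# --------------------------------------------------------------------------

def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and persist the results bundle.

    Returns a dict with the in-memory artifacts (cohort, fit, targets,
    incidence, summary text, manifest).  A stage failure propagates after
    upstream outputs have been written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs
    if config.simulate is not None:
        sim = generate_cohort(config.simulate)
        steps, bmi = sim.steps, sim.bmi
        genetics, covariates = sim.genetics, sim.covariates
    else:
        steps = pd.read_csv(config.steps_csv, parse_dates=["date"])
        bmi = pd.read_csv(config.bmi_csv, parse_dates=["date"])
        genetics = pd.read_csv(config.genetics_csv)
        covariates = pd.read_csv(config.covariates_csv)

    ages = covariates.set_index("person_id")["age"] if "age" in covariates else None

    # ---- curation
    valid, day_audit = filter_valid_days(steps, ages=ages, config=config.curation)
    monthly = monthly_means(valid, config.curation)
    cohort, exposure, attrition = assemble_cohort(
        monthly, bmi, covariates=covariates, config=config.curation
    )
    attrition["day_audit"] = day_audit
    if cohort.empty:
        raise RuntimeError("curation produced an empty analytic cohort")

    # ---- genetic scores
    scores = build_score_set(genetics)
    cohort = cohort.merge(
        scores[["person_id", "prs_residual", "percentile"]], on="person_id", how="inner"
    )
    cohort.to_csv(outdir / "analytic_cohort.csv", index=False)
    (outdir / "attrition.json").write_text(
        json.dumps(attrition, indent=1, default=str))

    obesity_status = cohort["event"].astype(int).to_numpy()
    nag = None
    if 0 < obesity_status.mean() < 1:
        pc_cols = [c for c in genetics.columns if c.startswith("pc")]
        gen_sub = genetics.set_index("person_id").loc[cohort["person_id"]]
        cov_mat = np.column_stack([
            cohort["baseline_age"].to_numpy(dtype=float),
            (cohort["sex"] == "male").astype(float),
            gen_sub[pc_cols].to_numpy(dtype=float),
        ])
        nag = incremental_nagelkerke(
            obesity_status, cohort["prs_residual"].to_numpy(), cov_mat)

    # ---- model
    pooled, fit_report = fit_analysis_model(
        cohort, exposure, model=config.model, m=config.m_imputations,
        seed=config.seed, k_donors=config.k_donors,
    )
    (outdir / "fit.json").write_text(json.dumps({
        "fit": fit_to_dict(pooled), "report": fit_report,
        "nagelkerke": nag}, indent=1, default=float))

    # ---- inversion
    targets = steps_vs_prs_profile(
        pooled, config.percentiles,
        reference=(config.reference_percentile, None))
    strata_targets = None
    if config.model == "bmi_adjusted" and config.bmi_strata:
        strata_targets = steps_vs_prs_profile(
            pooled, config.percentiles, bmi_strata=config.bmi_strata,
            reference=(config.reference_percentile, None))
        targets = pd.concat([targets, strata_targets], ignore_index=True)
    targets.to_csv(outdir / "targets.csv", index=False)

    # ---- cumulative incidence
    completed0 = pmm_impute(cohort, m=1, seed=config.seed,
                            k_donors=config.k_donors)[0]
    cp = build_counting_process(completed0, exposure)
    baseline = breslow_baseline(pooled, cp)
    inc = incidence_table(
        pooled, baseline, percentiles=config.incidence_percentiles,
        step_levels=config.step_levels, times=config.years, seed=config.seed,
    )
    inc.to_csv(outdir / "incidence.csv", index=False)

    # ---- summary + manifest
    prs_con = hr_contrast(pooled, "prs_residual")
    steps_con = hr_contrast(pooled, "steps_current")
    inter = fit_report["interaction"]
    lines = [
        f"steppath v{__version__} run (seed {config.seed}, model {config.model})",
        f"analytic cohort: {len(cohort)} persons, {pooled.n_events} incident events",
        f"HR, 75th vs 25th PRS percentile: {prs_con['hr']:.2f} "
        f"(95% CI {prs_con['ci_low']:.2f}-{prs_con['ci_high']:.2f}; p={prs_con['p']:.2e})",
        f"HR, 75th vs 25th step-count percentile: {steps_con['hr']:.2f} "
        f"(95% CI {steps_con['ci_low']:.2f}-{steps_con['ci_high']:.2f}; p={steps_con['p']:.2e})",
        f"PRS x steps interaction chunk test: chi2={inter['chi2']:.2f}, "
        f"df={inter['df']}, p={inter['p']:.2f}",
    ]
    if nag is not None:
        lines.append(
            f"incremental Nagelkerke R2 for the PRS: {100 * nag['increment']:.1f}% "
            f"(beta={nag['prs_beta']:.2f})")
    mid = targets[targets["baseline_bmi_stratum"].isna()] \
        if "baseline_bmi_stratum" in targets else targets
    for pct in (25, 50, 75):
        row = mid[mid["prs_percentile"] == pct]
        if not row.empty and np.isfinite(row.iloc[0]["steps_at_unit_hr"] or np.nan):
            r = row.iloc[0]
            lines.append(
                f"steps/day at HR=1.00, PRS percentile {pct}: "
                f"{r['steps_at_unit_hr']:.0f} "
                f"(95% CI {r['ci_low']:.0f}-{r['ci_high']:.0f})")
    summary = "\n".join(lines) + "\n"
    (outdir / "summary.txt").write_text(summary)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "cohort": cohort,
        "exposure": exposure,
        "attrition": attrition,
        "fit": pooled,
        "fit_report": fit_report,
        "nagelkerke": nag,
        "targets": targets,
        "incidence": inc,
        "baseline": baseline,
        "summary": summary,
        "manifest": manifest,
        "contrasts": {"prs": prs_con, "steps": steps_con},
    }
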