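"""Shared fixtures: simulated cohorts and fitted models reused across the
suite (session-scoped, all seeded)."""

import numpy as np
import pandas as pd
import pytest

from steppath.synthetic import SimulationConfig, generate_cohort, analysis_frames
from steppath.cox import (
    ModelSpec, TermSpec, build_counting_process, default_model_spec,
    fit_cox_tv, select_linearity,
)

#: linear-truth model matching the generator's hazard (the recovery spec)
LINEAR_SPEC_TERMS = (
    TermSpec("steps_current", "linear", scale=1000.0),
    TermSpec("prs_residual", "linear"),
    TermSpec("baseline_age", "linear"),
    TermSpec("sex", "categorical", levels=("male",)),
    TermSpec("sbp", "linear"),
)


def linear_spec(interaction=None) -> ModelSpec:
    return ModelSpec(terms=LINEAR_SPEC_TERMS, interaction=interaction)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with daily records, for curation-level tests."""
    cfg = SimulationConfig(n_participants=150, follow_up_years=2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def linear_fit_large():
    """n=4000 linear-truth cohort and its fitted linear Cox model."""
    cfg = SimulationConfig(
        n_participants=4000, follow_up_years=5, seed=2024,
        documentation_only=False, missing_rate=0.0, emit_daily_records=False,
    )
    coh = generate_cohort(cfg)
    cohort, exposure = analysis_frames(coh)
    cp = build_counting_process(cohort, exposure)
    fit = fit_cox_tv(cp, linear_spec())
    return {"cohort": cohort, "exposure": exposure, "cp": cp, "fit": fit,
            "config": cfg, "sim": coh}


@pytest.fixture(scope="session")
def spline_fit_large():
    """n=4000 cohort fitted with the full primary model (splines,
    interaction, drop-to-linear applied)."""
    cfg = SimulationConfig(
        n_participants=4000, follow_up_years=5, seed=515,
        documentation_only=False, missing_rate=0.0, emit_daily_records=False,
    )
    coh = generate_cohort(cfg)
    cohort, exposure = analysis_frames(coh)
    cp = build_counting_process(cohort, exposure)
    spec = default_model_spec(cp)
    fit, reports = select_linearity(cp, spec)
    return {"cohort": cohort, "exposure": exposure, "cp": cp, "fit": fit,
            "linearity": reports, "config": cfg}


def tiny_counting_frame(rng, n_rows=6, p_event=0.5, n_cov=1):
    """Random no-ties single-interval dataset for oracle comparisons."""
    while True:
        stop = rng.uniform(0.5, 5.0, n_rows)
        if len(np.unique(stop)) == n_rows:
            break
    event = rng.random(n_rows) < p_event
    if not event.any():
        event[rng.integers(n_rows)] = True
    df = pd.DataFrame({
        "person_id": [f"p{i}" for i in range(n_rows)],
        "start": np.zeros(n_rows),
        "stop": stop,
        "event": event,
    })
    for j in range(n_cov):
        df[f"x{j}"] = rng.standard_normal(n_rows)
    return df
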