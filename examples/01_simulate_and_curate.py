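"""Generate a synthetic cohort and run the wearable-data curation rules.

Prints the day-level filter audit, monthly aggregation counts, and the
cohort attrition table.
"""

from steppath import (
    SimulationConfig, generate_cohort,
    filter_valid_days, monthly_means, assemble_cohort,
)

cfg = SimulationConfig(n_participants=400, follow_up_years=3, seed=1)
sim = generate_cohort(cfg)
print(f"simulated {cfg.n_participants} participants, "
      f"{len(sim.steps):,} step-days, {len(sim.bmi):,} BMI records")

ages = sim.covariates.set_index("person_id")["age"]
valid, audit = filter_valid_days(sim.steps, ages=ages)
print("\nday-level filter audit (10h wear, 100-45000 steps, age >= 18):")
for k, v in audit.items():
    print(f"  {k:>14}: {v:,}")

monthly = monthly_means(valid)
print(f"\nperson-months with >= 15 valid days: {len(monthly):,}")

cohort, exposure, attrition = assemble_cohort(
    monthly, sim.bmi, covariates=sim.covariates)
print("\nattrition (baseline BMI < 30, 6-month incident-obesity landmark):")
for k in ("input_persons", "no_exposure_months", "no_baseline_bmi",
          "baseline_obese", "event_before_landmark", "analytic_persons"):
    print(f"  {k:>22}: {attrition[k]}")
print(f"\nincident obesity events: {int(cohort['event'].sum())} "
      f"of {len(cohort)} analytic participants")
# Each event is the first EHR-documented BMI >= 30 at least 6 months after
# monitoring began, in a person non-obese when monitoring started.
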