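"""Build the case table: 28 lagged activity features + 2 sleep targets.

A case pairs the sleep durations of day d with aggregates (mean/min/max)
of each activity quantity over the 1, 2 and 3 days before d.  Days with
any missing activity value in the 3-day window, or missing sleep on day d,
yield no case.
"""

from actisleep import (
    CohortConfig,
    build_cases,
    eligibility_filter,
    generate_cohort,
    standardize_per_participant,
)

records = generate_cohort(
    CohortConfig(n_participants=4, days_per_participant=(25, 90), seed=7)
)
table = build_cases(records)
print(f"{len(records)} daily records -> {table.n_cases} complete cases")
print(f"features per case: {len(table.feature_names)}")
print("cases per participant:", table.participant_counts().to_dict())

included, excluded = eligibility_filter(table, min_days=30)
print(f"inclusion rule (> 30 cases): kept {included.df.participant_id.nunique()}, "
      f"excluded {excluded}")

pooled = standardize_per_participant(included)
print("pooled standardized table: per-participant means ~0, SDs = 1 "
      f"({pooled.n_cases} cases ready for group-level analysis)")

case = table.df.iloc[0]
print(f"\nexample case ({case.participant_id}, {case.date.date()}):")
for name in ("steps_mean_1d", "steps_min_3d", "steps_max_3d", "moderate_activity_mean_2d"):
    print(f"  {name:28s} {case[name]:>10.1f}")
print(f"  light sleep {case.light_sleep_s / 3600:.2f} h, deep sleep {case.deep_sleep_s / 3600:.2f} h")
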