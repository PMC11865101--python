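"""Generate a synthetic wearable-tracker cohort and write it as CSV.

Each participant gets consecutive daily records of step count, activity
durations (s) and light/deep sleep durations (s), with heterogeneous
habitual activity across participants and missing cells sprinkled in.
"""

import io

from actisleep import CohortConfig, generate_cohort, write_daily_records

config = CohortConfig(n_participants=6, days_per_participant=(40, 120), seed=42)
records = generate_cohort(config)

per_participant = records.groupby("participant_id")
print(f"{config.n_participants} participants, {len(records)} daily records")
print("median daily steps per participant (spread reflects between-person heterogeneity):")
print(per_participant["steps"].median().round(0).to_string())
sleep_h = (records["light_sleep_s"] + records["deep_sleep_s"]) / 3600
print(f"total sleep duration: median {sleep_h.median():.1f} h/day")
print(f"missing cells: {records.iloc[:, 2:].isna().to_numpy().mean():.1%} (target {config.missing_prob:.0%})")

buf = io.StringIO()
write_daily_records(records, buf)
print("\nfirst CSV lines:")
print("\n".join(buf.getvalue().splitlines()[:4]))
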