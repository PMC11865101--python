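"""Single-condition subgroup discovery scored by explained variance.

The search enumerates every threshold condition `feature <= t` / `>= t`
over all 28 features, keeps subgroups covering 10-90% of cases, and ranks
them by EV = 1 - SS_within/SS_total, the fraction of target variance the
subgroup/complement split explains.
"""

from actisleep import (
    CohortConfig,
    FeatureId,
    PlantedEffect,
    build_cases,
    discover_best,
    generate_cohort,
    rank_subgroups,
    render_condition_text,
)

fid = FeatureId("steps", "min", 3)
records = generate_cohort(
    CohortConfig(
        n_participants=1,
        days_per_participant=153,
        seed=11,
        missing_prob=0.0,
        planted_effects=(
            PlantedEffect("deep_sleep", fid, "<=", quantile=0.36, shift=1.0),
        ),
    )
)
table = build_cases(records)
print(f"{table.n_cases} cases; planted: deep sleep +1.0 SD when {fid.name} "
      "is below its 36% quantile")

best = discover_best(table, "deep_sleep")
print("\nbest subgroup:")
print(f"  condition : {render_condition_text(best.condition)}")
print(f"  size      : {best.size_frac:.0%} of cases ({best.n_cases}/{best.n_total})")
print(f"  quality   : EV = {best.quality:.3f}")
print(f"  normalized deep-sleep mean: {best.normalized_target_mean:.2f} "
      "(>1 = longer-than-usual deep sleep inside the subgroup)")

print("\ntop 5 ranked subgroups (correlated features cluster around the truth):")
top = rank_subgroups(table, "deep_sleep", top_k=5)
print(top[["feature", "operator", "threshold", "size_frac", "quality"]]
      .round({"threshold": 0, "size_frac": 2, "quality": 3}).to_string(index=False))
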