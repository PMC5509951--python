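"""Simulate a 300-participant cohort, score it, and categorize engagement.

Shows the full scoring path: synthetic usage logs -> subindices -> EI ->
cohort quartile cut-points -> poor/moderate/high categories -> per-period
decay profile.
"""
from mhealth_ei import (categorize_frame, cohort_cutpoints, combine_frame,
                        score_cohort, simulate_cohort, trend_table)
from mhealth_ei.synthetic_cohort import SimulationConfig

dataset, truth = simulate_cohort(SimulationConfig(seed=1))
scores = score_cohort(dataset)
results = combine_frame(scores)
cutpoints = cohort_cutpoints(results["ei"])
results = categorize_frame(results, cutpoints)

print(f"cohort: {len(results)} participants, "
      f"{len(dataset.sessions)} sessions, {len(dataset.messages)} messages")
print(f"EI mean {results['ei'].mean():.1f}, SD {results['ei'].std():.1f}, "
      f"range {results['ei'].min():.1f}-{results['ei'].max():.1f}")
print(f"quartile cut-points: Q1 = {cutpoints.q1:.1f}, Q3 = {cutpoints.q3:.1f}")
print("categories:", results["category"].value_counts().to_dict(),
      "(poor <= Q1, high >= Q3)")

print("\nper-period mean components (engagement decays as infants age):")
print(trend_table(scores).round(3).to_string(index=False))
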