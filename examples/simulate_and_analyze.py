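"""Simulate a study-2-sized cohort and run the full analysis pipeline.

53 synthetic participants complete 9 daily sessions: the engine offers
targets, agents pick one, rate motivation before and after, and their step
totals respond. The pipeline then cleans the rows, codes selections into
scale categories, and reports completeness, ICCs and frequencies.
"""

import stepcompare as sc

cohort = sc.simulate_cohort(sc.sim_config(2, seed=42))
report = sc.analyze_cohort(cohort, fit_models=False)

print(report.summary_text())
print("selection frequencies by scale category:")
freqs = report.frequencies
print(freqs[freqs.section == "type_of_target"][["category", "n", "pct"]]
      .to_string(index=False))
print(
    "\nThe ICCs give the share of each outcome's variance due to stable "
    "between-person differences; upward selections exceeding 50% mirrors "
    "the preference pattern the platform is designed to elicit."
)
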