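"""Generate one day's comparison-target options under each study-2 condition.

A participant who took 10,000 steps yesterday sees four profiles whose step
totals sit at fixed percentages of that anchor (with +/-2% obfuscation noise):
all below it, a mix, or all above it, depending on the day's condition.
"""

import numpy as np

import stepcompare as sc

rng = np.random.default_rng(7)
design = sc.study_design(2)
anchor = 10_000

for condition in design.condition_labels:
    profiles = sc.generate_target_set(anchor, condition, design, rng,
                                      with_details=False)
    print(f"\ncondition: {condition}")
    for p in profiles:
        print(f"  {p.username}: {p.displayed_steps:>6d} steps "
              f"(nominal {p.nominal_scale:.0%} of own, {p.direction})")

print(
    "\nEach displayed total is within 2% of its nominal percentage of the "
    "participant's previous-day steps; the direction label says whether the "
    "target out-stepped the participant."
)
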