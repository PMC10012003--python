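# Daily randomization among downward-only, mixed, and upward-only option sets.
study_id: 2
conditions:
  downward_only: [0.9, 0.8, 0.7, 0.6]
  mixed: [0.9, 0.8, 1.1, 1.2]
  upward_only: [1.1, 1.2, 1.3, 1.4]
options_per_day: 4
noise_halfwidth: 0.02
leaderboard: false
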