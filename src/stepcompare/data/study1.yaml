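# Pilot design: one fixed option set per day, 2 upward + 2 downward targets.
study_id: 1
conditions:
  fixed: [1.1, 1.3, 0.9, 0.7]
options_per_day: 4
noise_halfwidth: 0.02
leaderboard: false
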