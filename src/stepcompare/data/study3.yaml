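# Team leaderboard design: self + live teammate + fabricated third user,
# placed below both live totals, between them, or above both.
study_id: 3
conditions:
  fab_below: []
  fab_between: []
  fab_above: []
options_per_day: 2
noise_halfwidth: 0.02
leaderboard: true
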