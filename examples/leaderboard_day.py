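"""Build one team-design (study-3) leaderboard day.

Two live teammates are joined by a platform-fabricated third user placed 20%
below the lower live total, between the two, or 20% above the higher one.
"""

import numpy as np

import stepcompare as sc

rng = np.random.default_rng(11)
live_me, live_mate = 8200, 6100

for placement in ("fab_below", "fab_between", "fab_above"):
    fab = sc.generate_fabricated_steps(live_me, live_mate, placement, rng)
    board = sc.build_leaderboard(
        sc.LeaderboardEntry("me", live_me, is_self=True),
        [
            sc.LeaderboardEntry("mate01", live_mate),
            sc.LeaderboardEntry("fab99", fab, fabricated=True),
        ],
    )
    ranks = ", ".join(
        f"{e.username}={e.displayed_steps}" + ("*" if e.fabricated else "")
        for e in board.entries
    )
    print(f"{placement:12s} -> [{ranks}]  (my rank: {board.self_rank})")

print(
    "\nEntries descend by step total; * marks the fabricated user, whose "
    "placement is the randomized condition of the team design."
)
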