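"""Aggregate the packaged per-study selection tables.

The three studies' published selection-frequency tables ship with the
package; simple aggregations over them reproduce the headline selection
rates (upward-selection counts and shares, modal categories).
"""

import stepcompare as sc
from stepcompare.fixtures import selection_counts

tables = sc.load_fixture_tables()

print("study 1 (pilot, n=28 selections):")
print(f"  upward share: {sc.upward_share(tables['table3'])}%")

t4 = tables["table4"]
print(f"\nstudy 2 ({int(selection_counts(t4).sum())} selections):")
print(f"  upward selections: {sc.upward_selection_count(t4)}")
print(f"  modal category: {sc.modal_category(t4)}")

t5 = tables["table5"]
print(f"\nstudy 3 ({int(selection_counts(t5).sum())} selections):")
print(f"  share at or above own steps: {sc.upward_share(t5, inclusive=True)}%")
print(f"  modal category: {sc.modal_category(t5)}")

print(
    "\nUpward targets are selected more often than downward ones in every "
    "study, yet the modal single category can still be a downward one "
    "(90% in study 2) because upward selections spread over more categories."
)
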