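"""Packaged per-study selection summary tables and aggregations over them.

The three studies' published selection tables (frequencies of selected
scale categories with descriptive model estimates) ship with the package as
small CSV fixtures.  Values are preserved verbatim; where the study-1 table's
printed frequency column is internally inconsistent with its reported totals
(29 rows vs n=28), an ``n_text`` column carries the totals-consistent counts
and aggregations use those.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "load_fixture_tables",
    "category_midpoint",
    "selection_counts",
    "upward_selection_count",
    "upward_share",
    "modal_category",
]

_TABLES = ("table3", "table4", "table5")


def _read_packaged_csv(name: str) -> pd.DataFrame:
    text = resources.files("stepcompare.data").joinpath(f"{name}.csv").read_text()
    return pd.read_csv(StringIO(text))


def load_fixture_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged selection tables for studies 1-3.

    Keys ``table3`` (study 1), ``table4`` (study 2), ``table5`` (study 3).
    """
    return {name: _read_packaged_csv(name) for name in _TABLES}


def category_midpoint(label: str) -> float:
    """Numeric percentage a category label stands for (band midpoints for the
    wide upward bands)."""
    label = label.strip()
    bands = {"110%-199%": 155.0, "200%-999%": 600.0, "1000%-1999%": 1500.0,
             ">2000%": 2500.0}
    if label in bands:
        return bands[label]
    if label.endswith("%"):
        return float(label.rstrip("%"))
    raise InvalidInputError(f"unrecognized category label {label!r}")


def selection_counts(
    table: pd.DataFrame, use_text_counts: bool = True
) -> pd.Series:
    """Per-category selection counts from a fixture table's target section.

    Prefers the totals-consistent ``n_text`` column when present (study 1's
    printed column disagrees with its reported totals).
    """
    rows = table[table["section"] == "type_of_target"]
    col = "n_text" if (use_text_counts and "n_text" in rows.columns) else "n"
    return rows.set_index("category")[col].astype(int)


def upward_selection_count(
    table: pd.DataFrame, threshold: float = 100.0, inclusive: bool = False
) -> int:
    """Number of selections at categories above the participant's own steps.

    ``inclusive`` also counts the lateral (100%) category, the accounting
    under which the study-3 upward share reproduces its printed total.
    """
    counts = selection_counts(table)
    total = 0
    for label, n in counts.items():
        mid = category_midpoint(label)
        if mid > threshold or (inclusive and mid == threshold):
            total += int(n)
    return total


def upward_share(
    table: pd.DataFrame, inclusive: bool = False
) -> float:
    """Upward selections as a percentage of all selections (one decimal)."""
    counts = selection_counts(table)
    up = upward_selection_count(table, inclusive=inclusive)
    return round(100.0 * up / int(counts.sum()), 1)


def modal_category(table: pd.DataFrame) -> tuple[str, int]:
    """Most frequently selected scale category and its count."""
    counts = selection_counts(table, use_text_counts=False)
    label = counts.idxmax()
    return str(label), int(counts.loc[label])
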