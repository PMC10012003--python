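"""Data-preparation rules: cleaning filters, selection coding, centering.

The analysis table has one row per completed participant-day.  Cleaning
removes implausible telemetry (Details-page dwell over 6 minutes) and
non-wear step totals (under 100 steps/day); selection coding expresses the
chosen target's displayed steps as a percentage of the participant's own
previous-day steps rounded to the nearest 10; and person-mean centering
splits repeated measures into a between-person mean and a within-person
daily deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidInputError, UndefinedRatioError

__all__ = [
    "VIEWING_SECONDS_MAX",
    "STEPS_MIN",
    "filter_observations",
    "code_scale_category",
    "category_percentage",
    "person_mean_center",
    "CenteredVariable",
    "completeness_report",
    "build_day_table",
    "frequency_table",
]

VIEWING_SECONDS_MAX = 360.0  # strict: rows with viewing_seconds > 6 min are removed
STEPS_MIN = 100  # strict: rows with steps < 100 are removed (boundary retained)


def filter_observations(
    rows: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove implausible rows; report counts per rule.

    Rules are strict inequalities: ``viewing_seconds > 360`` and
    ``steps < 100``.  A row failing both rules is counted under both (the
    report is per rule, not a partition); ``total_removed`` counts unique rows.
    Filtering is idempotent.
    """
    if rows.empty:
        report = {"viewing_over_6min": 0, "steps_under_100": 0, "total_removed": 0}
        return rows.copy(), report
    over_view = rows["viewing_seconds"] > VIEWING_SECONDS_MAX
    under_steps = rows["steps"] < STEPS_MIN
    report = {
        "viewing_over_6min": int(over_view.sum()),
        "steps_under_100": int(under_steps.sum()),
        "total_removed": int((over_view | under_steps).sum()),
    }
    kept = rows.loc[~(over_view | under_steps)].copy()
    return kept, report


def category_percentage(selected_steps: int, own_prev_steps: int) -> int:
    """Selected target's steps as a percentage of own previous-day steps,
    rounded to the nearest 10.

    Exact .5 boundaries round away from 100% (95% -> 90, 105% -> 110), so the
    tie-break never pulls a selection toward the lateral category.
    """
    if own_prev_steps == 0:
        raise UndefinedRatioError(
            "scale percentage undefined: previous-day steps are zero"
        )
    if selected_steps < 0 or own_prev_steps < 0:
        raise InvalidInputError("step totals must be >= 0")
    pct = 100.0 * selected_steps / own_prev_steps
    tenths = pct / 10.0
    frac = tenths - math.floor(tenths)
    if abs(frac - 0.5) < 1e-9:  # exact tie: round away from 100%
        rounded = math.floor(tenths) if pct < 100.0 else math.ceil(tenths)
    else:
        rounded = math.floor(tenths + 0.5)
    return int(rounded * 10)


def code_scale_category(selected_steps: int, own_prev_steps: int) -> str:
    """Code a selection into its scale-category label.

    Percentages up to 200 keep their own ``"NN%"`` label; larger ones fall in
    the wide-range bands used when fabricated placements produce extreme
    ratios: ``200%-999%``, ``1000%-1999%`` and ``>2000%``.
    """
    pct = category_percentage(selected_steps, own_prev_steps)
    if pct <= 200:
        return f"{pct}%"
    if pct < 1000:
        return "200%-999%"
    if pct < 2000:
        return "1000%-1999%"
    return ">2000%"


@dataclass(frozen=True)
class CenteredVariable:
    """A repeated measure split into between- and within-person parts."""

    person_means: pd.Series  # index: participant id
    within_deviations: pd.Series  # aligned with the input rows
    between_values: pd.Series  # person mean broadcast to rows

    def reconstruct(self) -> pd.Series:
        return self.between_values + self.within_deviations


def person_mean_center(
    values: Sequence[float] | pd.Series,
    participant_ids: Sequence | pd.Series,
) -> CenteredVariable:
    """Person-mean centering: between part = each person's mean across days,
    within part = that day's value minus the person's mean."""
    values = pd.Series(np.asarray(values, dtype=float))
    ids = pd.Series(np.asarray(participant_ids))
    if len(values) != len(ids):
        raise InvalidInputError("values and participant_ids differ in length")
    if len(values) == 0:
        empty = pd.Series(dtype=float)
        return CenteredVariable(empty, empty, empty)
    means = values.groupby(ids.values).mean()
    between = ids.map(means).astype(float)
    within = values - between.values
    return CenteredVariable(
        person_means=means, within_deviations=within, between_values=between
    )


def completeness_report(
    n_participants: int, n_days_expected: int, n_observed: int
) -> float:
    """Percentage of expected participant-days with no completed session."""
    if n_participants < 1 or n_days_expected < 1:
        raise InvalidInputError("n_participants and n_days_expected must be >= 1")
    expected = n_participants * n_days_expected
    if n_observed > expected:
        raise ConsistencyError(
            f"observed {n_observed} rows exceed the {expected} expected"
        )
    return 100.0 * (expected - n_observed) / expected


def build_day_table(
    steps: pd.DataFrame,
    sessions: Sequence[Mapping],
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the tidy analysis table, one row per completed participant-day.

    ``steps`` carries participant_id, day_index, steps.  ``sessions`` are the
    JSONL records written by the simulator (or the platform): raw SessionLog
    fields plus the day's offer context.  Sessions without a final selection
    are dropped (the day is incomplete).  Demographics, when given, are merged
    and age is centered at the grand mean.
    """
    from .designs import TargetProfile
    from .telemetry import SessionLog, derive_session_metrics

    step_lookup = {
        (r.participant_id, int(r.day_index)): int(r.steps)
        for r in steps.itertuples()
    }
    rows = []
    for rec in sessions:
        if not rec.get("final_selection"):
            continue  # abandoned session: logged but excluded from metrics
        log = SessionLog.from_dict(rec)
        offered = [TargetProfile.from_dict(p) for p in rec["offered"]]
        prev = int(rec["prev_day_steps"])
        metrics = derive_session_metrics(log, offered, prev)
        rows.append(
            {
                "participant_id": log.participant_id,
                "day_index": log.day_index,
                "steps": step_lookup.get((log.participant_id, log.day_index)),
                "prev_day_steps": prev,
                "m_pre": log.m_pre,
                "m_post": log.m_post,
                "motivation_change": metrics.motivation_change,
                "viewing_seconds": metrics.viewing_seconds,
                "elements_viewed": metrics.elements_viewed,
                "selected_username": metrics.selected_username,
                "selected_steps": metrics.selected_steps,
                "selected_direction": metrics.selected_direction,
                "selected_scale_category": metrics.selected_scale_category,
                "condition_label": rec.get("condition_label"),
                "fabricated_selected": metrics.fabricated_selected,
                "first_equals_final": metrics.first_equals_final,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.dropna(subset=["steps"]).reset_index(drop=True)
    table["steps"] = table["steps"].astype(int)
    if demographics is not None and not demographics.empty:
        table = table.merge(demographics, on="participant_id", how="left")
        if "age" in table.columns:
            table["age_c"] = table["age"] - table["age"].mean()
    return table


def _category_sort_key(label: str) -> tuple[int, float]:
    if label.endswith("%") and not label.startswith(">") and "-" not in label:
        return (0, float(label.rstrip("%")))
    order = {"110%-199%": 145.0, "200%-999%": 600.0, "1000%-1999%": 1500.0, ">2000%": 2500.0}
    return (1, order.get(label, math.inf))


def frequency_table(day_table: pd.DataFrame) -> pd.DataFrame:
    """Selections by scale category with descriptive outcome summaries.

    One row per observed category plus downward/upward aggregate rows, in the
    shape of the per-study selection tables: n, percentage of selections, and
    mean (SE) of motivation change and steps per day.
    """
    if day_table.empty:
        return pd.DataFrame(
            columns=["section", "category", "n", "pct", "motiv_mean", "motiv_se",
                     "steps_mean", "steps_se"]
        )
    total = len(day_table)

    def _summary(section: str, label: str, sub: pd.DataFrame) -> dict:
        out = {
            "section": section,
            "category": label,
            "n": len(sub),
            "pct": round(100.0 * len(sub) / total, 1),
        }
        for col, prefix in (("motivation_change", "motiv"), ("steps", "steps")):
            if col in sub.columns and len(sub):
                vals = sub[col].astype(float)
                out[f"{prefix}_mean"] = vals.mean()
                out[f"{prefix}_se"] = (
                    vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else np.nan
                )
        return out

    rows = []
    cats = sorted(day_table["selected_scale_category"].unique(), key=_category_sort_key)
    for cat in cats:
        rows.append(
            _summary("type_of_target", cat,
                     day_table[day_table["selected_scale_category"] == cat])
        )
    for direction in ("downward", "upward"):
        sub = day_table[day_table["selected_direction"] == direction]
        if len(sub):
            rows.append(_summary("direction", direction, sub))
    if "condition_label" in day_table.columns:
        for label, sub in day_table.groupby("condition_label", dropna=True):
            rows.append(_summary("options_shown", str(label), sub))
    return pd.DataFrame(rows)
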