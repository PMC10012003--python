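"""End-to-end analysis pipeline: clean, code, center, decompose, model.

Orchestrates the preparation and multilevel layers over one simulated (or
recorded) dataset: filters implausible rows, codes selection categories,
reports completeness, computes empty-model ICCs for the four day-level
outcomes, builds the per-study selection frequency table, and fits the
standard day-level association models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError, StepCompareError
from .mlm import (
    ModelResult,
    fit_day_level_model,
    variance_components,
    within_between_association,
)
from .prep import (
    build_day_table,
    completeness_report,
    filter_observations,
    frequency_table,
)
from .simulate import CohortData

__all__ = ["AnalysisReport", "analyze_cohort", "analyze_dataset"]

ICC_OUTCOMES = ("viewing_seconds", "elements_viewed", "motivation_change", "steps")


@dataclass
class AnalysisReport:
    """All pipeline outputs for one dataset."""

    day_table: pd.DataFrame  # cleaned analysis rows
    removal_report: dict[str, int]
    missing_pct: float
    icc: dict[str, float]
    frequencies: pd.DataFrame
    models: dict[str, ModelResult] = field(default_factory=dict)

    def summary_text(self) -> str:
        lines = ["analysis summary", "================", ""]
        lines.append(f"rows analyzed: {len(self.day_table)}")
        lines.append(
            "removed: "
            f"{self.removal_report['viewing_over_6min']} over 6 min viewing, "
            f"{self.removal_report['steps_under_100']} under 100 steps"
        )
        lines.append(f"missing participant-days: {self.missing_pct:.1f}%")
        lines.append("")
        lines.append("empty-model ICCs:")
        for k, v in self.icc.items():
            lines.append(f"  {k}: {v:.3f}")
        lines.append("")
        up = self.day_table["selected_direction"] == "upward"
        if len(self.day_table):
            lines.append(
                f"upward selections: {int(up.sum())}/{len(self.day_table)} "
                f"({100.0 * up.mean():.1f}%)"
            )
        for name, res in self.models.items():
            lines.append("")
            lines.append(f"model: {name} (n={res.n_obs}, persons={res.n_persons})")
            for term, row in res.params.iterrows():
                lines.append(
                    f"  {term}: B={row['B']:.3f} SE={row['SE']:.3f} "
                    f"t({int(row['df'])})={row['t']:.2f} p={row['p']:.3f}"
                )
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cleaned": out / "cleaned.csv",
            "frequencies": out / "frequencies.csv",
            "icc": out / "icc.csv",
            "report": out / "report.txt",
        }
        self.day_table.to_csv(paths["cleaned"], index=False)
        self.frequencies.to_csv(paths["frequencies"], index=False)
        pd.Series(self.icc, name="icc").rename_axis("outcome").to_csv(paths["icc"])
        paths["report"].write_text(self.summary_text())
        for name, res in self.models.items():
            p = out / f"model_{name}.csv"
            res.params.rename_axis("term").to_csv(p)
            paths[f"model_{name}"] = p
        return paths


def analyze_cohort(
    cohort: CohortData,
    n_participants: int | None = None,
    n_days: int | None = None,
    fit_models: bool = True,
) -> AnalysisReport:
    """Run the full preparation and modeling pipeline on one dataset."""
    raw = cohort.day_table()
    if raw.empty:
        raise InvalidInputError("dataset contains no completed sessions")
    n_participants = n_participants or int(cohort.steps["participant_id"].nunique())
    n_days = n_days or int(cohort.steps["day_index"].nunique())
    missing_pct = completeness_report(n_participants, n_days, len(raw))
    clean, removal = filter_observations(raw)
    if clean.empty:
        raise InvalidInputError("no rows survive the cleaning filters")

    icc = {}
    for outcome in ICC_OUTCOMES:
        if outcome in clean.columns:
            try:
                icc[outcome] = variance_components(
                    clean[outcome], clean["participant_id"]
                ).icc
            except InvalidInputError:
                pass

    freqs = frequency_table(clean)
    models: dict[str, ModelResult] = {}
    if fit_models:
        covariates = [c for c in ("age_c", "gender", "race") if c in clean.columns]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if clean["condition_label"].nunique() > 1:
                for outcome, name in (
                    ("motivation_change", "motivation_by_options"),
                    ("steps", "steps_by_options"),
                ):
                    try:
                        models[name] = fit_day_level_model(
                            clean, outcome, ["condition_label"], covariates
                        )
                    except StepCompareError:
                        pass
            if clean["motivation_change"].std() > 0:
                try:
                    models["steps_on_motivation_within"] = within_between_association(
                        clean, "steps", "motivation_change", covariates
                    )
                except StepCompareError:
                    pass
    return AnalysisReport(
        day_table=clean,
        removal_report=removal,
        missing_pct=missing_pct,
        icc=icc,
        frequencies=freqs,
        models=models,
    )


def analyze_dataset(data_dir: str | Path, **kwargs) -> AnalysisReport:
    """Load a dataset directory written by the simulator and analyze it."""
    cohort = CohortData.read(data_dir)
    return analyze_cohort(cohort, **kwargs)
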