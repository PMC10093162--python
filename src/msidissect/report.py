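"""Cohort descriptive statistics and Mascot-export score filtering.

Dispersion is the population standard deviation (n denominator): it is the
convention that reproduces both printed cohort SD pairs exactly, whereas the
sample SD does not. All reported values are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .segment import round_half_up


@dataclass
class CohortSummary:
    """Descriptive statistics of the clinical table."""

    n: int
    mean_age: float
    sd_age: float
    mean_size: float
    sd_size: float
    fraction_advanced_fibrosis: float  # percent

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_age_years": self.mean_age,
            "sd_age_years": self.sd_age,
            "mean_size_mm": self.mean_size,
            "sd_size_mm": self.sd_size,
            "advanced_fibrosis_pct": self.fraction_advanced_fibrosis,
        }


def _pop_sd(values: np.ndarray) -> float:
    return float(np.sqrt(np.mean((values - values.mean()) ** 2)))


def cohort_summary(table: pd.DataFrame | str | Path) -> CohortSummary:
    """Mean / population SD of age and tumor size, and the advanced-fibrosis
    percentage, rounded half-up to one decimal."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    if table.empty:
        raise ValueError("empty cohort table")
    ages = table["age_years"].to_numpy(dtype=float)
    sizes = table["tumor_size_mm"].to_numpy(dtype=float)
    fib = table["advanced_fibrosis"].astype(str).str.strip().str.lower().eq("yes")
    return CohortSummary(
        n=len(table),
        mean_age=round_half_up(float(ages.mean()), 1),
        sd_age=round_half_up(_pop_sd(ages), 1),
        mean_size=round_half_up(float(sizes.mean()), 1),
        sd_size=round_half_up(_pop_sd(sizes), 1),
        fraction_advanced_fibrosis=round_half_up(100.0 * fib.mean(), 1),
    )


def filter_mascot_export(
    table: pd.DataFrame | str | Path,
    min_score: float = 56.0,
    score_column: str = "score",
) -> pd.DataFrame:
    """Keep rows with score strictly greater than ``min_score`` (the printed
    positive-identification threshold is exclusive)."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    if score_column not in table.columns:
        raise ValueError(f"missing score column {score_column!r} in Mascot export")
    return table[table[score_column] > min_score].reset_index(drop=True)
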