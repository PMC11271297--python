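"""Five-fiscal-year budget impact for the public healthcare system.

The treated population combines the five-year prevalent pool (year 1 only)
with the annual incident cohort, filtered to early-stage, HER2-positive
disease and a coverage fraction. Each treated cohort contributes the
strategy's undiscounted public-perspective per-cycle cost stream from the
cohort model, aligned to its start year; a fiscal year's budget sums the
active cohorts' stream slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import run_strategy
from .parameters import ParameterSet
from .states import Perspective

__all__ = ["EpidemiologyInputs", "BIAResult", "eligible_cohorts", "run_bia"]


@dataclass(frozen=True)
class EpidemiologyInputs:
    """Population inputs (defaults: published Sri Lankan figures)."""

    prevalent_cases_5yr: float = 13_647.0
    annual_incident_cases: float = 4_447.0
    pct_early: float = 0.66
    pct_her2_positive: float = 0.22
    coverage: float = 0.60

    def __post_init__(self) -> None:
        if self.prevalent_cases_5yr <= 0 or self.annual_incident_cases <= 0:
            raise ValueError("case counts must be positive")
        for name in ("pct_early", "pct_her2_positive", "coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def eligible_cohorts(epi: EpidemiologyInputs, years: int = 5) -> np.ndarray:
    """Treated patients starting in each fiscal year (fractional, unrounded).

    Year 1 treats both the prevalent pool and the incident cohort; later
    years treat the incident cohort only.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    frac = epi.pct_early * epi.pct_her2_positive * epi.coverage
    counts = np.full(years, epi.annual_incident_cases * frac)
    counts[0] = (epi.prevalent_cases_5yr + epi.annual_incident_cases) * frac
    return counts


@dataclass(frozen=True)
class BIAResult:
    """Annual budgets per strategy with incrementals and ratios vs the
    comparator; LKR and USD, in millions."""

    comparator: str
    coverage: float
    frame: pd.DataFrame

    def year1_incremental_lkr_millions(self, strategy_id: str) -> float:
        row = self.frame[
            (self.frame.strategy_id == strategy_id) & (self.frame.year == 1)
        ]
        return float(row["incremental_lkr_millions"].iloc[0])

    def budget_ratio(self, strategy_id: str, year: int) -> float:
        row = self.frame[
            (self.frame.strategy_id == strategy_id) & (self.frame.year == year)
        ]
        return float(row["ratio_vs_comparator"].iloc[0])


def run_bia(
    params: ParameterSet,
    epi: EpidemiologyInputs | None = None,
    years: int = 5,
    comparator: str = "S1",
) -> BIAResult:
    """Budget impact over ``years`` fiscal years, public perspective.

    A cohort starting in fiscal year j contributes months ``12*(y-j)`` to
    ``12*(y-j)+11`` of its undiscounted cost stream to fiscal year y.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if epi is None:
        epi = EpidemiologyInputs()
    counts = eligible_cohorts(epi, years)

    rows = []
    budgets: dict[str, np.ndarray] = {}
    for strategy in params.strategies:
        stream = run_strategy(strategy.id, params, Perspective.PUBLIC).per_cycle_cost_stream
        annual = np.zeros(years)
        for year in range(1, years + 1):
            total = 0.0
            for j in range(1, year + 1):
                offset = 12 * (year - j)
                total += counts[j - 1] * stream[offset : offset + 12].sum()
            annual[year - 1] = total
        budgets[strategy.id] = annual
    ref = budgets[comparator]
    for sid, annual in budgets.items():
        for year in range(1, years + 1):
            b = annual[year - 1]
            rows.append(
                {
                    "strategy_id": sid,
                    "year": year,
                    "budget_lkr_millions": b / 1e6,
                    "budget_usd_millions": b / params.lkr_per_usd / 1e6,
                    "incremental_lkr_millions": (b - ref[year - 1]) / 1e6,
                    "incremental_usd_millions": (b - ref[year - 1])
                    / params.lkr_per_usd
                    / 1e6,
                    "ratio_vs_comparator": b / ref[year - 1] if ref[year - 1] else np.nan,
                }
            )
    return BIAResult(comparator=comparator, coverage=epi.coverage, frame=pd.DataFrame(rows))
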