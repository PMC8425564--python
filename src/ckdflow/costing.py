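"""Direct annual costs of the projected CKD population.

Yearly stage counts are multiplied by the per-patient annual cost of the
stage; the diabetes treatment add-on applies to the diabetic sub-stock of
every state (including ESKD), and scenario treatment costs apply to their
eligible sub-stocks.  Costs are evaluated on start-of-year stocks, so the
first model year's cost is a pure function of the initial condition.
Discounting at the configured annual rate starts after the first year:
year index 0 is undiscounted and year index t is divided by (1+r)^t.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CostTable
from .model import StageStocks
from .scenarios import ScenarioSpec
from .stages import ESKD, STAGES


def discount(cost: float, rate: float, year_index: int) -> float:
    """Present value of a cost incurred ``year_index`` years after start."""
    if year_index < 0:
        raise ValueError(f"year_index must be >= 0, got {year_index}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return cost / (1.0 + rate) ** year_index


def annual_cost(stocks: StageStocks, costs: CostTable,
                scenario: ScenarioSpec | None = None) -> dict[str, float]:
    """Undiscounted cost per state (GBP) for one year's stocks."""
    out: dict[str, float] = {}
    dm_addon = costs.dm_addon.mean
    for stage in STAGES:
        total = (stocks.stage_count(stage) * costs.annual_cost_by_stage[stage].mean
                 + stocks.stage_dm_count(stage) * dm_addon)
        out[stage] = total
    out[ESKD] = (stocks.eskd * costs.annual_cost_by_stage[ESKD].mean
                 + stocks.eskd_dm * dm_addon)
    if scenario is not None:
        for (stage, elig), cost_param in scenario.added_costs.items():
            eligible = (stocks.stage_dm_count(stage) if elig == "dm_only"
                        else stocks.stage_count(stage))
            out[stage] += eligible * cost_param.mean
    return out


def project_costs(trajectory: list[StageStocks], years: list[int],
                  costs: CostTable, scenario: ScenarioSpec | None,
                  rate: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-state cost table and totals for a recorded trajectory.

    Returns
    -------
    per_state : DataFrame
        Undiscounted GBP by calendar year (rows) and state (columns).
    totals : DataFrame
        Columns ``total`` and ``total_discounted`` in GBP.
    """
    rows = [annual_cost(st, costs, scenario) for st in trajectory]
    per_state = pd.DataFrame(rows, index=years)
    per_state.index.name = "year"
    total = per_state.sum(axis=1)
    factors = np.array([1.0 / (1.0 + rate) ** t for t in range(len(years))])
    totals = pd.DataFrame(
        {"total": total, "total_discounted": total.to_numpy() * factors},
        index=per_state.index,
    )
    return per_state, totals
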