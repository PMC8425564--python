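"""Baseline and treatment scenarios as declarative schedule/cost modifiers.

A scenario lists progression hazard ratios and added per-patient annual
costs keyed by ``(stage, eligibility)``, where eligibility is either
``"dm_only"`` (the diabetic sub-stock, i.e. the medium and fast classes)
or ``"all"``.  The built-in intervention combines SGLT2 inhibitors for
diabetic stage 3a/3b (progression HR 0.71, 179.94 GBP/patient/yr) with
multidisciplinary pre-dialysis care for stages 4 and 5 (HR 0.85; 360.97
and 1637.46 GBP/patient/yr), at 100% uptake among the eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import CostTable, ParameterSet, UncertainParam
from .stages import CLASSES, STAGES

ELIGIBILITIES = ("dm_only", "all")

#: Class columns touched by each eligibility rule (slow = non-diabetic).
_ELIGIBLE_CLASSES = {"dm_only": ("medium", "fast"), "all": CLASSES}

BASELINE = "baseline"
SGLT2_PREDIALYSIS = "sglt2_predialysis"


@dataclass(frozen=True)
class ScenarioSpec:
    """Named set of progression-HR modifiers and added treatment costs."""

    name: str
    progression_hr: dict[tuple[str, str], UncertainParam] = field(default_factory=dict)
    added_costs: dict[tuple[str, str], UncertainParam] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.progression_hr, self.added_costs):
            for (stage, elig) in mapping:
                if stage not in STAGES:
                    raise ValueError(f"unknown stage {stage!r} in scenario")
                if elig not in ELIGIBILITIES:
                    raise ValueError(f"unknown eligibility {elig!r} in scenario")
        for key, hr in self.progression_hr.items():
            if hr.mean <= 0:
                raise ValueError(f"progression HR for {key} must be > 0")


def baseline_scenario() -> ScenarioSpec:
    return ScenarioSpec(name=BASELINE)


def intervention_scenario(params: ParameterSet, costs: CostTable) -> ScenarioSpec:
    """SGLT2 + pre-dialysis intervention built from the registry values."""
    return ScenarioSpec(
        name=SGLT2_PREDIALYSIS,
        progression_hr={
            ("3a", "dm_only"): params.sglt2_hr,
            ("3b", "dm_only"): params.sglt2_hr,
            ("4", "all"): params.predialysis_hr,
            ("5", "all"): params.predialysis_hr,
        },
        added_costs={
            ("3a", "dm_only"): costs.sglt2_cost,
            ("3b", "dm_only"): costs.sglt2_cost,
            ("4", "all"): costs.predialysis_cost_s4,
            ("5", "all"): costs.predialysis_cost_s5,
        },
    )


def builtin_scenarios(params: ParameterSet, costs: CostTable) -> list[ScenarioSpec]:
    """The two study scenarios: baseline and SGLT2 + pre-dialysis."""
    return [baseline_scenario(), intervention_scenario(params, costs)]


def apply_hr(p: float, hr: float, scale: str = "hazard") -> float:
    """Modify an annual exit probability by a hazard ratio.

    On the hazard scale ``p`` becomes ``1 - (1 - p)^HR`` (exact rate
    scaling of the implied constant hazard); the multiplicative variant
    ``min(HR * p, 1)`` is available for sensitivity comparison.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    if scale == "hazard":
        return 1.0 - (1.0 - p) ** hr
    if scale == "multiplicative":
        return min(hr * p, 1.0)
    raise ValueError(f"unknown hr scale {scale!r}")


def apply_scenario(schedule: pd.DataFrame, spec: ScenarioSpec,
                   hr_scale: str = "hazard",
                   hr_draws: dict[tuple[str, str], float] | None = None
                   ) -> pd.DataFrame:
    """Transition schedule with the scenario's hazard ratios applied.

    Eligibility is resolved through the class structure: ``dm_only``
    touches the medium and fast columns (the diabetic classes), ``all``
    every column.  ``hr_draws`` substitutes sampled HR values during PSA.
    """
    out = schedule.copy()
    for (stage, elig), hr_param in spec.progression_hr.items():
        hr = hr_param.mean if hr_draws is None else hr_draws[(stage, elig)]
        for cls in _ELIGIBLE_CLASSES[elig]:
            out.loc[stage, cls] = apply_hr(float(out.loc[stage, cls]), hr,
                                           scale=hr_scale)
    return out
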