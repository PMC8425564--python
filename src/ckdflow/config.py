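"""Typed, validated parameter registry for the projection model.

Every number the model consumes lives here: stage prevalences with their
95% CIs, albuminuria and diabetes proportions, incidence, growth,
eGFR-decline rates, age-band mortality, stage/diabetes mortality hazard
ratios, treatment-effect hazard ratios, and the annual per-patient cost
table.  A packaged YAML file carries the default values; a user config
supplies any subset of keys and is deep-merged over the defaults.

Scalar uncertain quantities are represented as :class:`UncertainParam`
(mean, 95% CI, sampling family) so the probabilistic sensitivity analysis
can rebuild a sampling distribution for each of them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .stages import AGE_BANDS, CLASSES, ESKD, STAGES

_DEFAULT_RESOURCE = "default_parameters.yaml"

#: Families available for PSA sampling.
FAMILIES = ("beta", "normal", "gamma", "fixed")

#: Width of a 95% normal CI in standard deviations (2 * 1.96).
CI_WIDTH_SD = 3.92


class ConfigError(ValueError):
    """Malformed configuration file (missing/unparseable keys)."""


class ValidationError(ConfigError):
    """A parameter value violates its documented bounds."""


@dataclass(frozen=True)
class UncertainParam:
    """A scalar parameter with mean, 95% CI and PSA distribution family."""

    mean: float
    ci_low: float
    ci_high: float
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValidationError(
                f"require ci_low <= mean <= ci_high, got "
                f"({self.ci_low}, {self.mean}, {self.ci_high})"
            )
        if self.family == "beta" and not (0.0 <= self.ci_low and self.ci_high <= 1.0):
            raise ValidationError(
                f"beta parameter CI must lie in [0, 1], got "
                f"({self.ci_low}, {self.ci_high})"
            )
        if self.family == "fixed" and not (self.ci_low == self.mean == self.ci_high):
            raise ValidationError(
                f"fixed parameter requires ci_low = mean = ci_high, got "
                f"({self.ci_low}, {self.mean}, {self.ci_high})"
            )

    @classmethod
    def fixed(cls, value: float) -> "UncertainParam":
        return cls(mean=value, ci_low=value, ci_high=value, family="fixed")

    @property
    def is_degenerate(self) -> bool:
        """True when the CI carries no width (point mass under PSA)."""
        return self.ci_low == self.ci_high

    @property
    def sd(self) -> float:
        """Normal-approximate standard deviation implied by the 95% CI."""
        return (self.ci_high - self.ci_low) / CI_WIDTH_SD

    def to_mapping(self) -> dict[str, Any]:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "family": self.family,
        }

    @classmethod
    def from_mapping(cls, obj: Any, *, key: str = "?") -> "UncertainParam":
        if isinstance(obj, (int, float)):
            return cls.fixed(float(obj))
        if not isinstance(obj, Mapping) or "mean" not in obj:
            raise ConfigError(f"parameter {key!r}: expected a number or a "
                              f"mapping with a 'mean' entry, got {obj!r}")
        mean = float(obj["mean"])
        family = str(obj.get("family", "fixed"))
        lo = obj.get("ci_low", mean if family == "fixed" else None)
        hi = obj.get("ci_high", mean if family == "fixed" else None)
        if lo is None or hi is None:
            raise ConfigError(f"parameter {key!r}: non-fixed family requires "
                              f"ci_low and ci_high")
        try:
            return cls(mean=mean, ci_low=float(lo), ci_high=float(hi), family=family)
        except ValidationError as err:
            raise ValidationError(f"parameter {key!r}: {err}") from None


def pmp_to_proportion(rate_pmp: float) -> float:
    """Convert a per-million-population annual rate to a proportion/year."""
    if rate_pmp < 0:
        raise ValidationError(f"pmp rate must be >= 0, got {rate_pmp}")
    return rate_pmp / 1_000_000.0


@dataclass(frozen=True)
class ParameterSet:
    """Epidemiological and structural parameters of the projection."""

    stage_prevalence: dict[str, UncertainParam]
    albuminuria_by_stage: dict[str, UncertainParam]
    dm_prevalence_ckd: UncertainParam
    incidence_3a: UncertainParam          # proportion of incidence_population / year
    adult_growth_rate: float
    decline_rates: dict[str, float]       # ml/min/1.73m2 per year, by class
    mortality_by_age: dict[str, float]    # per 1000 / year, by age band
    age_weights: dict[str, float]         # proportions summing to 1
    mortality_hr: dict[tuple[str, bool], UncertainParam]   # (stage, has_dm)
    esrd_mortality: UncertainParam        # annual death probability on RRT
    esrd_initial_count: float
    initial_stage_counts: dict[str, float] | None
    base_population_40plus: float
    incidence_population: float           # denominator of the pmp incidence
    egfr_slope: float                     # fitted b of ln(count) = a + b*eGFR
    egfr_intercept: float                 # fitted a
    discount_rate: float
    horizon_years: int
    start_year: int
    sglt2_hr: UncertainParam
    predialysis_hr: UncertainParam
    dm_incidence: UncertainParam | None = None   # config hook, unused by default
    cycle_order: str = "mortality_first"  # or "progression_first"
    rrt_uptake: float = 1.0               # fraction of stage-5 exits starting RRT
    hr_scale: str = "hazard"              # or "multiplicative"

    def __post_init__(self) -> None:
        for stage in STAGES:
            if stage not in self.stage_prevalence:
                raise ConfigError(f"stage_prevalence missing stage {stage!r}")
            if stage not in self.albuminuria_by_stage:
                raise ConfigError(f"albuminuria_by_stage missing stage {stage!r}")
        for name, p in self._proportion_params().items():
            if not (0.0 <= p.ci_low and p.ci_high <= 1.0):
                raise ValidationError(
                    f"{name} must lie in [0, 1], got CI ({p.ci_low}, {p.ci_high})"
                )
        for cls in CLASSES:
            if cls not in self.decline_rates:
                raise ConfigError(f"decline_rates missing class {cls!r}")
            if self.decline_rates[cls] < 0:
                raise ValidationError(f"decline_rates[{cls}] must be >= 0")
        for band in AGE_BANDS:
            if band not in self.mortality_by_age:
                raise ConfigError(f"mortality_by_age missing band {band!r}")
            if band not in self.age_weights:
                raise ConfigError(f"age_weights missing band {band!r}")
        total_w = sum(self.age_weights.values())
        if abs(total_w - 1.0) > 1e-9:
            raise ValidationError(f"age_weights must sum to 1, got {total_w}")
        for stage in STAGES:
            for dm in (False, True):
                if (stage, dm) not in self.mortality_hr:
                    raise ConfigError(f"mortality_hr missing ({stage}, dm={dm})")
                if self.mortality_hr[(stage, dm)].mean <= 0:
                    raise ValidationError(f"mortality_hr[{stage}, dm={dm}] must be > 0")
        if self.horizon_years < 1:
            raise ValidationError(f"horizon_years must be >= 1, got {self.horizon_years}")
        if self.base_population_40plus <= 0:
            raise ValidationError("base_population_40plus must be > 0")
        if self.incidence_population <= 0:
            raise ValidationError("incidence_population must be > 0")
        if not (0.0 <= self.rrt_uptake <= 1.0):
            raise ValidationError(f"rrt_uptake must lie in [0, 1], got {self.rrt_uptake}")
        if self.cycle_order not in ("mortality_first", "progression_first"):
            raise ConfigError(f"unknown cycle_order {self.cycle_order!r}")
        if self.hr_scale not in ("hazard", "multiplicative"):
            raise ConfigError(f"unknown hr_scale {self.hr_scale!r}")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")

    def _proportion_params(self) -> dict[str, UncertainParam]:
        out = {f"stage_prevalence[{s}]": p for s, p in self.stage_prevalence.items()}
        out.update(
            {f"albuminuria_by_stage[{s}]": p
             for s, p in self.albuminuria_by_stage.items()}
        )
        out["dm_prevalence_ckd"] = self.dm_prevalence_ckd
        out["incidence_3a"] = self.incidence_3a
        out["esrd_mortality"] = self.esrd_mortality
        return out


@dataclass(frozen=True)
class CostTable:
    """Annual per-patient direct costs in GBP (Chilean system, 2019 basis)."""

    annual_cost_by_stage: dict[str, UncertainParam]   # stages + ESKD
    dm_addon: UncertainParam
    sglt2_cost: UncertainParam
    predialysis_cost_s4: UncertainParam
    predialysis_cost_s5: UncertainParam

    def __post_init__(self) -> None:
        for state in STAGES + (ESKD,):
            if state not in self.annual_cost_by_stage:
                raise ConfigError(f"annual_cost_by_stage missing state {state!r}")
        for name, p in self._all().items():
            if p.mean < 0:
                raise ValidationError(f"cost {name} must be >= 0, got {p.mean}")

    def _all(self) -> dict[str, UncertainParam]:
        out = dict(self.annual_cost_by_stage)
        out.update(
            dm_addon=self.dm_addon,
            sglt2=self.sglt2_cost,
            predialysis_stage4=self.predialysis_cost_s4,
            predialysis_stage5=self.predialysis_cost_s5,
        )
        return out


def _cost_param(obj: Any, *, key: str) -> UncertainParam:
    """Cost entry: bare means get the +-20% gamma CI used by the PSA."""
    if isinstance(obj, Mapping) and "ci_low" in obj:
        return UncertainParam.from_mapping(obj, key=key)
    mean = float(obj["mean"] if isinstance(obj, Mapping) else obj)
    if mean == 0.0:
        return UncertainParam.fixed(0.0)
    return UncertainParam(
        mean=mean, ci_low=0.8 * mean, ci_high=1.2 * mean, family="gamma"
    )


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config_mapping() -> dict:
    """Raw mapping of the packaged default configuration."""
    text = (resources.files("ckdflow.data") / _DEFAULT_RESOURCE).read_text()
    return yaml.safe_load(text)


def _strkeys(mapping: Mapping) -> dict:
    """YAML reads an unquoted stage key like ``4:`` as an integer."""
    return {str(k): v for k, v in mapping.items()}


def _parse(raw: Mapping) -> tuple[ParameterSet, CostTable]:
    try:
        model = raw["model"]
        pop = raw["population"]
        epi = raw["epidemiology"]
        prog = raw["progression"]
        mort = raw["mortality"]
        costs_raw = raw["costs"]
        scen = raw["scenarios"]
    except KeyError as err:
        raise ConfigError(f"missing top-level config section {err.args[0]!r}") from None

    def up(section: Mapping, key: str) -> UncertainParam:
        if key not in section:
            raise ConfigError(f"missing config key {key!r}")
        return UncertainParam.from_mapping(section[key], key=key)

    prev_raw = _strkeys(epi.get("stage_prevalence", {}))
    stage_prev = {
        s: UncertainParam.from_mapping(v, key=f"stage_prevalence[{s}]")
        for s, v in prev_raw.items()
    }
    alb_raw = _strkeys(epi.get("albuminuria_by_stage", {}))
    alb = {
        s: UncertainParam.from_mapping(v, key=f"albuminuria_by_stage[{s}]")
        for s, v in alb_raw.items()
    }
    # The pmp entry is converted to a proportion before validation, so the
    # beta-family [0, 1] bound applies on the proportion scale.
    if "incidence_3a_pmp" not in epi:
        raise ConfigError("missing config key 'incidence_3a_pmp'")
    inc_raw = epi["incidence_3a_pmp"]
    if not isinstance(inc_raw, Mapping):
        inc_raw = {"mean": inc_raw, "ci_low": inc_raw, "ci_high": inc_raw,
                   "family": "fixed"}
    incidence = UncertainParam(
        mean=pmp_to_proportion(float(inc_raw["mean"])),
        ci_low=pmp_to_proportion(float(inc_raw.get("ci_low", inc_raw["mean"]))),
        ci_high=pmp_to_proportion(float(inc_raw.get("ci_high", inc_raw["mean"]))),
        family=str(inc_raw.get("family", "fixed")),
    )
    hr = {}
    for dm, key in ((False, "hr_no_dm"), (True, "hr_dm")):
        table = _strkeys(mort[key])
        for s in STAGES:
            hr[(s, dm)] = UncertainParam.from_mapping(
                table[s], key=f"mortality.{key}[{s}]"
            )
    init_counts = epi.get("initial_stage_counts")
    if init_counts is not None:
        init_counts = {str(s): float(c) for s, c in init_counts.items()}
    dm_inc = epi.get("dm_incidence")
    params = ParameterSet(
        stage_prevalence=stage_prev,
        albuminuria_by_stage=alb,
        dm_prevalence_ckd=up(epi, "dm_prevalence_ckd"),
        incidence_3a=incidence,
        adult_growth_rate=float(pop["adult_growth_rate"]),
        decline_rates={c: float(v) for c, v in prog["decline_rates"].items()},
        mortality_by_age={str(b): float(v)
                          for b, v in mort["rates_per_1000"].items()},
        age_weights={str(b): float(v) for b, v in pop["age_weights"].items()},
        mortality_hr=hr,
        esrd_mortality=up(mort, "esrd_annual_probability"),
        esrd_initial_count=float(epi["esrd_initial_count"]),
        initial_stage_counts=init_counts,
        base_population_40plus=float(pop["base_population_40plus"]),
        incidence_population=float(pop["incidence_population"]),
        egfr_slope=float(prog["egfr_slope"]),
        egfr_intercept=float(prog["egfr_intercept"]),
        discount_rate=float(model["discount_rate"]),
        horizon_years=int(model["horizon_years"]),
        start_year=int(model["start_year"]),
        sglt2_hr=up(scen, "sglt2_hr"),
        predialysis_hr=up(scen, "predialysis_hr"),
        dm_incidence=(UncertainParam.from_mapping(dm_inc, key="dm_incidence")
                      if dm_inc is not None else None),
        cycle_order=str(model.get("cycle_order", "mortality_first")),
        rrt_uptake=float(model.get("rrt_uptake", 1.0)),
        hr_scale=str(model.get("hr_scale", "hazard")),
    )
    cost_table = CostTable(
        annual_cost_by_stage={
            s: _cost_param(v, key=f"cost[{s}]")
            for s, v in _strkeys(costs_raw["annual_by_stage"]).items()
        },
        dm_addon=_cost_param(costs_raw["dm_addon"], key="dm_addon"),
        sglt2_cost=_cost_param(costs_raw["sglt2"], key="sglt2"),
        predialysis_cost_s4=_cost_param(costs_raw["predialysis_stage4"],
                                        key="predialysis_stage4"),
        predialysis_cost_s5=_cost_param(costs_raw["predialysis_stage5"],
                                        key="predialysis_stage5"),
    )
    return params, cost_table


def load_parameters(config_path: str | Path | None = None
                    ) -> tuple[ParameterSet, CostTable]:
    """Load the parameter registry, merging a user config over the defaults.

    Parameters
    ----------
    config_path
        Optional YAML (or JSON, a YAML subset) file.  Keys present override
        the packaged defaults; everything else falls back to the default
        values.  ``None`` loads the defaults untouched.

    Returns
    -------
    (ParameterSet, CostTable)
        Fully validated registries.

    Raises
    ------
    ConfigError
        Missing or unparseable keys.
    ValidationError
        A value violating its documented bounds (the message names the
        offending field and the bound).
    """
    raw = default_config_mapping()
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            user = yaml.safe_load(path.read_text())
        except yaml.YAMLError as err:
            raise ConfigError(f"cannot parse config {path}: {err}") from None
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"config {path} must be a mapping at top level")
        raw = _deep_merge(raw, user)
    return _parse(raw)


def serialize(params: ParameterSet, costs: CostTable) -> dict:
    """Mapping form of a registry; inverse of :func:`load_parameters`."""
    hr_no_dm = {s: params.mortality_hr[(s, False)].to_mapping() for s in STAGES}
    hr_dm = {s: params.mortality_hr[(s, True)].to_mapping() for s in STAGES}
    inc = params.incidence_3a
    mapping = {
        "model": {
            "start_year": params.start_year,
            "horizon_years": params.horizon_years,
            "discount_rate": params.discount_rate,
            "cycle_order": params.cycle_order,
            "rrt_uptake": params.rrt_uptake,
            "hr_scale": params.hr_scale,
        },
        "population": {
            "base_population_40plus": params.base_population_40plus,
            "incidence_population": params.incidence_population,
            "adult_growth_rate": params.adult_growth_rate,
            "age_weights": dict(params.age_weights),
        },
        "epidemiology": {
            "stage_prevalence": {s: p.to_mapping()
                                 for s, p in params.stage_prevalence.items()},
            "initial_stage_counts": (dict(params.initial_stage_counts)
                                     if params.initial_stage_counts else None),
            "esrd_initial_count": params.esrd_initial_count,
            "albuminuria_by_stage": {s: p.to_mapping()
                                     for s, p in params.albuminuria_by_stage.items()},
            "dm_prevalence_ckd": params.dm_prevalence_ckd.to_mapping(),
            "incidence_3a_pmp": {
                "mean": inc.mean * 1e6, "ci_low": inc.ci_low * 1e6,
                "ci_high": inc.ci_high * 1e6, "family": inc.family,
            },
            "dm_incidence": (params.dm_incidence.to_mapping()
                             if params.dm_incidence else None),
        },
        "progression": {
            "decline_rates": dict(params.decline_rates),
            "egfr_intercept": params.egfr_intercept,
            "egfr_slope": params.egfr_slope,
        },
        "mortality": {
            "rates_per_1000": dict(params.mortality_by_age),
            "hr_no_dm": hr_no_dm,
            "hr_dm": hr_dm,
            "esrd_annual_probability": params.esrd_mortality.to_mapping(),
        },
        "costs": {
            "annual_by_stage": {s: p.to_mapping()
                                for s, p in costs.annual_cost_by_stage.items()},
            "dm_addon": costs.dm_addon.to_mapping(),
            "sglt2": costs.sglt2_cost.to_mapping(),
            "predialysis_stage4": costs.predialysis_cost_s4.to_mapping(),
            "predialysis_stage5": costs.predialysis_cost_s5.to_mapping(),
        },
        "scenarios": {
            "sglt2_hr": params.sglt2_hr.to_mapping(),
            "predialysis_hr": params.predialysis_hr.to_mapping(),
        },
    }
    return mapping


def save_parameters(params: ParameterSet, costs: CostTable,
                    path: str | Path) -> None:
    """Write a registry back to YAML (round-trips through load_parameters)."""
    Path(path).write_text(yaml.safe_dump(serialize(params, costs), sort_keys=False))
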