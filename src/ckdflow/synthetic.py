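"""Synthetic survey-style inputs for exercising the estimation steps.

The projection's upstream inputs are cross-sectional: a histogram of
discrete eGFR values below 60 and per-stage prevalences / comorbidity
proportions estimated from health-survey microdata.  This module
generates microdata with exactly the statistical structure the analysis
assumes — an exponential eGFR density within stages, stage membership by
prevalence, and diabetes/albuminuria flags independent given stage — so
the histogram fit and the prevalence estimators can be tested end to end
without the real survey.

What the generator does *not* emulate: complex survey design (strata,
clusters, weights), non-response, serum-creatinine measurement error, or
correlation between diabetes and albuminuria beyond the configured
stage-specific proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ParameterSet, UncertainParam
from .egfr import EGFR_RANGE, EgfrHistogram
from .stages import AGE_BANDS, STAGE_BOUNDS, STAGES


def gen_egfr_histogram(slope: float, intercept: float, noise_sd: float,
                       seed: int) -> EgfrHistogram:
    """Histogram with counts exp(a + b*x + eps) for x in 1..59.

    ``eps ~ Normal(0, noise_sd)`` independently per bin; ``noise_sd = 0``
    reproduces the model exactly, so the log-linear fit recovers (a, b).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    x = np.arange(EGFR_RANGE[0], EGFR_RANGE[1] + 1)
    eps = rng.normal(0.0, noise_sd, size=x.size) if noise_sd > 0 else 0.0
    count = np.exp(intercept + slope * x + eps)
    return EgfrHistogram(egfr=x, count=count)


@dataclass
class SyntheticSurvey:
    """Survey-style records plus the generation metadata."""

    data: pd.DataFrame        # columns egfr, dm, albuminuria, age_band, stage
    seed: int
    n: int
    params_used: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.data[["egfr", "dm", "albuminuria", "age_band"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SyntheticSurvey":
        df = pd.read_csv(path)
        df["stage"] = [_stage_of(e) for e in df["egfr"]]
        return cls(data=df, seed=-1, n=len(df))


def _stage_of(egfr: float) -> str:
    for stage, (lo, hi) in STAGE_BOUNDS.items():
        if lo <= egfr < hi:
            return stage
    return "none"


def _sample_truncated_exponential(rng: np.random.Generator, lo: float,
                                  hi: float, slope: float, size: int
                                  ) -> np.ndarray:
    """Draws from a density proportional to exp(slope*x) on [lo, hi)."""
    u = rng.random(size)
    if slope == 0.0:
        return lo + u * (hi - lo)
    # inverse CDF of the truncated exponential tilt
    return lo + np.log1p(u * np.expm1(slope * (hi - lo))) / slope


def gen_survey(n: int, params: ParameterSet, seed: int) -> SyntheticSurvey:
    """Generate ``n`` survey records from the registry's parameters.

    Stage membership (including "no CKD") is drawn from the stage
    prevalences; eGFR within a stage follows the exponential density with
    the registry's slope; diabetes and albuminuria are Bernoulli with the
    stage's proportions (independent given stage); non-CKD records get an
    eGFR uniform on [60, 120) and background comorbidity rates.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    prev = np.array([params.stage_prevalence[s].mean for s in STAGES])
    p_none = 1.0 - prev.sum()
    stage_idx = rng.choice(len(STAGES) + 1, size=n,
                           p=np.append(prev, p_none))
    egfr = np.empty(n)
    dm = np.zeros(n, dtype=bool)
    alb = np.zeros(n, dtype=bool)
    dm_prev = params.dm_prevalence_ckd.mean
    for i, stage in enumerate(STAGES):
        mask = stage_idx == i
        k = int(mask.sum())
        if k == 0:
            continue
        lo, hi = STAGE_BOUNDS[stage]
        egfr[mask] = _sample_truncated_exponential(
            rng, max(lo, 1e-6), hi, params.egfr_slope, k
        )
        dm[mask] = rng.random(k) < dm_prev
        alb[mask] = rng.random(k) < params.albuminuria_by_stage[stage].mean
    none_mask = stage_idx == len(STAGES)
    k = int(none_mask.sum())
    egfr[none_mask] = rng.uniform(60.0, 120.0, size=k)
    dm[none_mask] = rng.random(k) < 0.123     # background adult DM prevalence
    alb[none_mask] = rng.random(k) < 0.05
    bands = list(AGE_BANDS)
    weights = np.array([params.age_weights[b] for b in bands])
    age_band = rng.choice(bands, size=n, p=weights / weights.sum())
    stage_labels = np.array(list(STAGES) + ["none"])[stage_idx]
    df = pd.DataFrame({"egfr": egfr, "dm": dm, "albuminuria": alb,
                       "age_band": age_band, "stage": stage_labels})
    return SyntheticSurvey(data=df, seed=seed, n=n,
                           params_used={"dm_prevalence": dm_prev})


class EmptyCellError(ValueError):
    """A stage has no records, so its proportion is undefined."""


def _proportion(successes: float, total: float, name: str) -> UncertainParam:
    if total == 0:
        raise EmptyCellError(f"no records to estimate {name}")
    p = successes / total
    se = np.sqrt(max(p * (1.0 - p), 0.0) / total)
    lo = min(max(p - 1.96 * se, 0.0), p)
    hi = max(min(p + 1.96 * se, 1.0), p)
    family = "beta" if lo < hi else "fixed"
    return UncertainParam(mean=p, ci_low=lo, ci_high=hi, family=family)


def estimate_parameters(survey: SyntheticSurvey) -> dict:
    """Unweighted prevalence/proportion estimates with normal 95% CIs.

    Returns a partial parameter mapping (stage prevalences, per-stage
    albuminuria proportions, diabetes prevalence in CKD) in the same
    :class:`UncertainParam` form the registry uses.
    """
    df = survey.data
    if len(df) == 0:
        raise EmptyCellError("empty survey")
    n = len(df)
    ckd = df[df["stage"] != "none"]
    out = {
        "stage_prevalence": {}, "albuminuria_by_stage": {},
    }
    for stage in STAGES:
        in_stage = df["stage"] == stage
        out["stage_prevalence"][stage] = _proportion(
            float(in_stage.sum()), float(n), f"stage_prevalence[{stage}]"
        )
        sub = df[in_stage]
        out["albuminuria_by_stage"][stage] = _proportion(
            float(sub["albuminuria"].sum()), float(len(sub)),
            f"albuminuria_by_stage[{stage}]",
        )
    out["dm_prevalence_ckd"] = _proportion(
        float(ckd["dm"].sum()), float(len(ckd)), "dm_prevalence_ckd"
    )
    return out
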