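"""Log-linear eGFR density and the derived annual transition fractions.

The number of people at each discrete eGFR value below 60 is well
described by an exponential density: an ordinary least-squares fit of
``ln(count)`` on eGFR gives ``ln(y) = a + b*x``.  Within a stage's eGFR
band ``[L, U)`` the standing population is therefore distributed as
``exp(b*x)``, and with a constant annual decline of ``d`` ml/min/1.73m2
the individuals within ``d`` of the lower bound leave the stage during
the year.  That yields the closed-form annual exit fraction

    f(d) = (e^{b(L+d)} - e^{bL}) / (e^{bU} - e^{bL})
         = expm1(b*d) / expm1(b*(U-L)),

clipped to 1 when ``d`` exceeds the band width, and degenerating to
``d / (U - L)`` as ``b -> 0``.  Note the fraction depends on the band
only through its width, a direct consequence of the exponential form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stages import CLASSES, STAGE_BOUNDS, STAGES

EGFR_RANGE = (1, 59)   # discrete eGFR values used for the density fit


class InsufficientDataError(ValueError):
    """Fewer than two usable (positive-count) histogram bins."""


@dataclass(frozen=True)
class EgfrHistogram:
    """Counts of persons at each discrete eGFR value in [1, 59]."""

    egfr: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        egfr = np.asarray(self.egfr, dtype=float)
        count = np.asarray(self.count, dtype=float)
        object.__setattr__(self, "egfr", egfr)
        object.__setattr__(self, "count", count)
        if egfr.shape != count.shape or egfr.ndim != 1:
            raise ValueError("egfr and count must be 1-D arrays of equal length")
        if np.unique(egfr).size != egfr.size:
            raise ValueError("egfr values must be unique")
        lo, hi = EGFR_RANGE
        if egfr.size and (egfr.min() < lo or egfr.max() > hi):
            raise ValueError(f"egfr values must lie in [{lo}, {hi}]")
        if np.any(count < 0):
            raise ValueError("counts must be >= 0")

    def to_csv(self, path) -> None:
        pd.DataFrame({"egfr": self.egfr.astype(int), "count": self.count}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EgfrHistogram":
        df = pd.read_csv(path)
        return cls(egfr=df["egfr"].to_numpy(), count=df["count"].to_numpy())


@dataclass(frozen=True)
class EgfrDensityFit:
    """OLS fit of ln(count) on eGFR: intercept ``a`` and slope ``b``."""

    intercept: float
    slope: float


def fit_log_linear(hist: EgfrHistogram) -> EgfrDensityFit:
    """Fit ``ln(count) = a + b*eGFR`` by ordinary least squares.

    Zero-count bins are excluded (their logarithm is undefined); at least
    two positive bins are required.
    """
    mask = hist.count > 0
    x = hist.egfr[mask]
    y = np.log(hist.count[mask])
    if x.size < 2:
        raise InsufficientDataError(
            f"need >= 2 positive-count bins to fit, got {x.size}"
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    a, b = model.params
    return EgfrDensityFit(intercept=float(a), slope=float(b))


def predict_count(fit: EgfrDensityFit, egfr: float) -> float:
    """Predicted number of persons at an eGFR value: exp(a + b*eGFR)."""
    return float(np.exp(fit.intercept + fit.slope * np.asarray(egfr, dtype=float)))


def transition_fraction(bounds: tuple[float, float], decline: float,
                        slope: float) -> float:
    """Annual fraction of a stage's stock crossing its lower eGFR bound.

    Parameters
    ----------
    bounds
        Stage eGFR band ``(lower, upper)`` with ``lower < upper``.
    decline
        Annual eGFR decline d >= 0 (ml/min/1.73m2 per year).
    slope
        Exponential density slope b; ``b = 0`` gives the uniform limit
        ``d / (upper - lower)``.
    """
    lower, upper = bounds
    if lower >= upper:
        raise ValueError(f"require lower < upper, got {bounds}")
    if decline < 0:
        raise ValueError(f"decline must be >= 0, got {decline}")
    width = upper - lower
    if decline >= width:
        return 1.0
    if slope == 0.0:
        return decline / width
    # expm1 keeps the ratio continuous and accurate as b -> 0.
    frac = np.expm1(slope * decline) / np.expm1(slope * width)
    return float(min(max(frac, 0.0), 1.0))


def build_transition_schedule(fit: EgfrDensityFit,
                              decline_rates: dict[str, float]) -> pd.DataFrame:
    """Per-stage, per-class annual exit fractions.

    Returns a DataFrame indexed by stage ('3a', '3b', '4', '5') with one
    column per progression class.  Stage-5 exits flow to ESKD; all other
    exits flow to the next stage.
    """
    missing = [c for c in CLASSES if c not in decline_rates]
    if missing:
        raise ValueError(f"decline_rates missing classes: {missing}")
    data = {
        cls: [transition_fraction(STAGE_BOUNDS[s], decline_rates[cls], fit.slope)
              for s in STAGES]
        for cls in CLASSES
    }
    return pd.DataFrame(data, index=list(STAGES), columns=list(CLASSES))
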