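"""Growth-rate estimation from in vivo Chl-a fluorescence time series.

The maximum specific growth rate mu (d^-1) is the steepest slope of an
ordinary least-squares regression of ln(RFU) on time over a sliding
window of consecutive readings (default four time points, falling back
to all readings when fewer are available, with an absolute minimum of
two).  Interval rates over e.g. a 24-h stain incubation use
ln(F_end/F_start)/dt with linear interpolation in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_io import FluorescenceSeries
from .errors import InsufficientDataError, InvalidInputError, InvalidIntervalError

__all__ = ["GrowthFit", "HarvestFlag", "max_growth_rate", "growth_over_interval", "harvest_flag"]


@dataclass(frozen=True)
class GrowthFit:
    """One log-linear regression window and its slope (mu, d^-1)."""

    mu: float
    intercept: float  # ln(RFU) at t = 0
    window: tuple[float, float]  # (t_start, t_end) in days
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise InvalidInputError("window must satisfy t_start < t_end")
        if self.n_points < 2:
            raise InvalidInputError("a fit needs >= 2 points")


class HarvestFlag(str, Enum):
    NOT_READY = "not_ready"
    MID_EXPONENTIAL = "mid_exponential"
    STATIONARY = "stationary"


def _ols_loglinear(t: np.ndarray, ln_f: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of ln(F) ~ t.  sst == 0 -> r^2 of 1 (exact fit)."""
    tb = t.mean()
    yb = ln_f.mean()
    sxx = float(np.sum((t - tb) ** 2))
    sxy = float(np.sum((t - tb) * (ln_f - yb)))
    slope = sxy / sxx
    intercept = yb - slope * tb
    sst = float(np.sum((ln_f - yb) ** 2))
    ssr = float(np.sum((ln_f - (intercept + slope * t)) ** 2))
    if sst <= 1e-300:
        r2 = 1.0
    else:
        r2 = max(0.0, 1.0 - ssr / sst)
    return slope, intercept, r2


def max_growth_rate(series: FluorescenceSeries, window_size: int = 4) -> GrowthFit:
    """Best (steepest) log-linear window fit of a well's growth curve.

    Windows are runs of consecutive readings; slope ties break to the
    earliest window.  With fewer readings than ``window_size`` all are
    used (minimum two).
    """
    if window_size < 2:
        raise InvalidInputError("window_size must be >= 2")
    n = len(series)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 readings, got {n}")
    w = min(window_size, n)
    ln_f = np.log(series.rfu)
    best: GrowthFit | None = None
    for i in range(n - w + 1):
        t = series.times[i : i + w]
        y = ln_f[i : i + w]
        slope, intercept, r2 = _ols_loglinear(t, y)
        if best is None or slope > best.mu:
            best = GrowthFit(
                mu=slope,
                intercept=intercept,
                window=(float(t[0]), float(t[-1])),
                n_points=w,
                r_squared=r2,
            )
    assert best is not None
    return best


def growth_over_interval(series: FluorescenceSeries, t_start: float, t_end: float) -> float:
    """ln(F_end / F_start) / (t_end - t_start), interpolating in ln space."""
    if not t_end > t_start:
        raise InvalidIntervalError(f"t_end ({t_end}) must exceed t_start ({t_start})")
    if t_start < series.times[0] or t_end > series.times[-1]:
        raise InvalidIntervalError(
            f"interval [{t_start}, {t_end}] outside readings "
            f"[{series.times[0]}, {series.times[-1]}]"
        )
    ln_f = np.log(series.rfu)
    ln_start = float(np.interp(t_start, series.times, ln_f))
    ln_end = float(np.interp(t_end, series.times, ln_f))
    return (ln_end - ln_start) / (t_end - t_start)


def harvest_flag(
    series: FluorescenceSeries,
    slope_fraction: float = 0.8,
    growth_multiple: float = 4.0,
    near_zero_mu: float = 0.05,
    min_growth_mu: float = 0.1,
    window_size: int = 4,
) -> HarvestFlag:
    """Classify a well as not ready, mid-exponential, or stationary.

    Mid-exponential: the trailing-window slope is still within
    ``slope_fraction`` of the historical maximum slope AND the culture has
    grown at least ``growth_multiple``-fold from its initial reading.
    Stationary: the trailing slope has decayed to ``near_zero_mu`` after
    growth (max slope >= ``min_growth_mu``) was observed.
    """
    if len(series) < 3:
        raise InsufficientDataError("need >= 3 readings to assess phase")
    w = min(window_size, len(series))
    ln_f = np.log(series.rfu)
    trailing, _, _ = _ols_loglinear(series.times[-w:], ln_f[-w:])
    max_mu = max_growth_rate(series, window_size=window_size).mu
    grew = max_mu >= min_growth_mu
    if grew and trailing <= near_zero_mu:
        return HarvestFlag.STATIONARY
    if (
        grew
        and trailing >= slope_fraction * max_mu
        and series.rfu[-1] >= growth_multiple * series.rfu[0]
    ):
        return HarvestFlag.MID_EXPONENTIAL
    return HarvestFlag.NOT_READY
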