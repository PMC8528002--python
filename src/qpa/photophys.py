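"""Rapid-light-curve (RLC) analysis: relative ETR and P-I curve fitting.

A PAM fluorometer exposes the sample to eight increasing irradiance steps
(0 to ~1878 umol photons m^-2 s^-1) and records the effective quantum
yield Y at each.  Relative electron transport rate is ETR = Y * E * 0.5
(half the photons assumed to reach PSII; absorptance is not measured, so
ETR is in relative units throughout).

The photosynthesis-irradiance model fitted is the exponential saturation
curve with an optional photoinhibition term:

    ETR(E) = Ps * (1 - exp(-alpha * E / Ps)) * exp(-beta * E / Ps)

With beta = 0 the scale parameter Ps equals ETRmax; with beta > 0,

    ETRmax = Ps * [alpha/(alpha+beta)] * [beta/(alpha+beta)]^(beta/alpha)

The minimum saturating irradiance is Ik = ETRmax / alpha, an identity the
returned fit satisfies exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InsufficientDataError, InvalidInputError

__all__ = [
    "RapidLightCurve",
    "RLCFit",
    "SaturationStatus",
    "relative_etr",
    "platt_etr",
    "etrmax_from_params",
    "fit_rlc",
    "saturation_check",
    "DEFAULT_E_STEPS",
]

#: Default irradiance staircase (umol photons m^-2 s^-1), 8 steps, 0..1878.
DEFAULT_E_STEPS: tuple[float, ...] = (0.0, 66.0, 131.0, 248.0, 438.0, 719.0, 1187.0, 1878.0)


@dataclass
class RapidLightCurve:
    """Eight ordered (irradiance, effective quantum yield) steps of one run."""

    irradiance: np.ndarray
    yields: np.ndarray
    saturated: np.ndarray | None = None  # per-step detector saturation flags
    dilution_fraction: float = 0.50  # 50% standard, 25% for bright samples

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.saturated is None:
            self.saturated = np.zeros(len(self.irradiance), dtype=bool)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        if not (len(self.irradiance) == len(self.yields) == len(self.saturated)):
            raise InvalidInputError("irradiance, yields and saturated must align")
        if self.irradiance[0] != 0 or np.any(np.diff(self.irradiance) <= 0):
            raise InvalidInputError("irradiance steps must be strictly increasing from 0")
        if np.any((self.yields < 0) | (self.yields > 1)):
            raise InvalidInputError("effective quantum yields must lie in [0, 1]")
        if self.dilution_fraction not in (0.50, 0.25):
            raise InvalidInputError("dilution_fraction must be 0.50 or 0.25")

    def etr(self, etr_factor: float = 0.5) -> np.ndarray:
        return relative_etr(self.yields, self.irradiance, etr_factor)


@dataclass(frozen=True)
class RLCFit:
    """Fitted P-I parameters; ik == etrmax / alpha exactly."""

    alpha: float
    etrmax: float
    ik: float
    beta: float
    ps: float
    rss: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.etrmax > 0):
            raise InvalidInputError("alpha and etrmax must be > 0")


class SaturationStatus(str, Enum):
    OK = "ok"
    OVERSATURATED = "oversaturated"


def relative_etr(yields, irradiance, etr_factor: float = 0.5):
    """Relative electron transport rate: yield x irradiance x etr_factor."""
    y = np.asarray(yields, dtype=float)
    e = np.asarray(irradiance, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise InvalidInputError("yield outside [0, 1]")
    if np.any(e < 0):
        raise InvalidInputError("irradiance must be >= 0")
    out = y * e * etr_factor
    return float(out) if out.ndim == 0 else out


def platt_etr(e, alpha: float, ps: float, beta: float = 0.0):
    """Model ETR at irradiance ``e`` (exponential saturation x photoinhibition)."""
    e = np.asarray(e, dtype=float)
    return ps * (1.0 - np.exp(-alpha * e / ps)) * np.exp(-beta * e / ps)


def etrmax_from_params(alpha: float, ps: float, beta: float) -> float:
    """Peak of the P-I curve; equals Ps when there is no photoinhibition."""
    if beta <= 0:
        return ps
    ab = alpha + beta
    return ps * (alpha / ab) * (beta / ab) ** (beta / alpha)


def saturation_check(curve: RapidLightCurve) -> SaturationStatus:
    """Flag curves whose metadata marks any detector-saturated step."""
    return (
        SaturationStatus.OVERSATURATED
        if bool(np.any(curve.saturated))
        else SaturationStatus.OK
    )


def _fit_once(e, etr, x0, bounds) -> tuple[np.ndarray, float] | None:
    try:
        res = least_squares(
            lambda p: platt_etr(e, *p) - etr,
            x0=x0,
            bounds=bounds,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
    except Exception:
        return None
    if not res.success and not np.isfinite(res.cost):
        return None
    return res.x, float(2 * res.cost)


def fit_rlc(
    curve: RapidLightCurve,
    etr_factor: float = 0.5,
    beta_rss_tolerance: float = 1e-2,
) -> RLCFit:
    """Multi-start nonlinear least squares of the P-I model to one RLC.

    Both the two-parameter (beta = 0) and three-parameter submodels are
    fitted; photoinhibition is kept only when it improves the residual sum
    of squares by more than ``beta_rss_tolerance`` (relative).  Raises
    :class:`FitFailureError` when no start converges, so the caller can
    mark the photophysiology traits missing for that well.
    """
    if saturation_check(curve) is SaturationStatus.OVERSATURATED:
        raise InvalidInputError("curve flagged oversaturated; re-run at 25% dilution")
    e = curve.irradiance
    etr = curve.etr(etr_factor)
    if len(e) < 5:
        raise InsufficientDataError(f"need >= 5 usable steps, got {len(e)}")
    if np.any(etr < 0):
        raise InvalidInputError("negative ETR input")
    if np.all(etr <= 0):
        raise FitFailureError("no positive ETR values; cannot fit")

    nz = np.nonzero(e)[0]
    alpha0 = max(etr[nz[0]] / e[nz[0]], 1e-6)
    etr_peak = float(etr.max())
    tiny = 1e-12

    starts3 = [
        (alpha0 * a_m, etr_peak * p_m, b0)
        for a_m in (1.0, 2.0)
        for p_m in (1.0, 1.5, 3.0)
        for b0 in (tiny, 0.05 * alpha0)
    ]
    starts2 = [(alpha0 * a_m, etr_peak * p_m) for a_m in (1.0, 2.0) for p_m in (1.0, 1.5, 3.0)]

    best2 = best3 = None
    for x0 in starts2:
        r = _fit_once(e, etr, x0, ([tiny, tiny], [np.inf, np.inf]))
        if r is not None and (best2 is None or r[1] < best2[1]):
            best2 = r
    for x0 in starts3:
        r = _fit_once(e, etr, x0, ([tiny, tiny, 0.0], [np.inf, np.inf, np.inf]))
        if r is not None and (best3 is None or r[1] < best3[1]):
            best3 = r
    if best2 is None and best3 is None:
        raise FitFailureError("P-I fit failed to converge from every start")

    use3 = (
        best3 is not None
        and best2 is not None
        and best3[1] < best2[1] * (1.0 - beta_rss_tolerance)
    ) or best2 is None
    if use3:
        (alpha, ps, beta), rss = best3
    else:
        (alpha, ps), rss = best2
        beta = 0.0
    etrmax = etrmax_from_params(alpha, ps, beta)
    return RLCFit(
        alpha=float(alpha),
        etrmax=float(etrmax),
        ik=float(etrmax / alpha),
        beta=float(beta),
        ps=float(ps),
        rss=rss,
    )
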