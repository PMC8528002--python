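"""Flow-cytometry trait derivation.

Cells are separated from background/debris by minimum chlorophyll (red
fluorescence) and forward-scatter thresholds.  Median forward scatter is
converted to an equivalent spherical diameter (ESD, um) through a linear
bead calibration FSC = slope * diameter + intercept fitted on beads of
known size.  From the gated population the module derives: cell size,
granularity (median side scatter), size-normalised chlorophyll content,
neutral-lipid stain delta (BODIPY, green channel), silicification
(PDMPO uptake per unit growth, UV channel), cell concentration, and a
QC-bead normalisation for cross-experiment comparability.

Medians use the lower-median convention for even event counts so results
are always an observed instrument value and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import EventTable
from .errors import (
    CalibrationRangeError,
    DegenerateCalibrationError,
    InsufficientCellsError,
    InvalidInputError,
    MissingMetadataError,
    QualityWarning,
)

__all__ = [
    "GateSpec",
    "BeadCalibration",
    "gate_events",
    "fit_bead_calibration",
    "estimate_size",
    "median_channel",
    "chla_per_size",
    "lipid_content",
    "silicification",
    "cell_concentration",
    "bead_normalize",
    "PAPER_CALIBRATION",
]

#: Minimum gated events for a robust population median.
DEFAULT_MIN_CELLS = 200


@dataclass(frozen=True)
class GateSpec:
    """Minimum Chl-a (red) and forward-scatter thresholds for the cell gate."""

    min_fl_red: float = 0.0
    min_fsc: float = 0.0

    def __post_init__(self) -> None:
        if self.min_fl_red < 0 or self.min_fsc < 0:
            raise InvalidInputError("gate thresholds must be >= 0")


@dataclass(frozen=True)
class BeadCalibration:
    """Linear FSC-vs-diameter calibration: FSC = slope * size + intercept."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    diameters: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise InvalidInputError(f"calibration slope must be > 0, got {self.slope}")

    def fsc_at(self, size_um: float) -> float:
        return self.slope * size_um + self.intercept

    def size_at(self, fsc: float) -> float:
        return (fsc - self.intercept) / self.slope


#: Calibration constants of the instrument the assay was developed on,
#: i.e. size = (FSC + 275549) / 83539.
PAPER_CALIBRATION = BeadCalibration(slope=83539.0, intercept=-275549.0)


def gate_events(events: EventTable, gate: GateSpec) -> EventTable:
    """Keep events above both thresholds; acquisition volume is preserved."""
    mask = (events.fl_red >= gate.min_fl_red) & (events.fsc >= gate.min_fsc)
    return events.subset(mask)


def fit_bead_calibration(
    bead_medians: list[tuple[float, float]],
) -> BeadCalibration:
    """Least-squares line through (diameter, median FSC) bead points."""
    if len(bead_medians) < 2:
        raise DegenerateCalibrationError("need >= 2 bead points")
    d = np.array([b[0] for b in bead_medians], dtype=float)
    f = np.array([b[1] for b in bead_medians], dtype=float)
    if len(np.unique(d)) < 2:
        raise DegenerateCalibrationError("need >= 2 distinct bead diameters")
    res = stats.linregress(d, f)
    if not res.slope > 0:
        raise DegenerateCalibrationError(
            f"nonpositive calibration slope {res.slope}; check bead medians"
        )
    return BeadCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        diameters=tuple(sorted(set(d.tolist()))),
    )


def median_channel(events: EventTable, channel: str) -> float:
    """Population median of one channel (lower median for even counts)."""
    x = events.channel(channel)
    n = len(x)
    if n == 0:
        raise InsufficientCellsError("empty event table")
    k = (n - 1) // 2
    return float(np.partition(x, k)[k])


def estimate_size(
    calib: BeadCalibration, events: EventTable, min_cells: int = DEFAULT_MIN_CELLS
) -> float:
    """Equivalent spherical diameter (um) from the gated population median FSC."""
    if events.n_events < min_cells:
        raise InsufficientCellsError(
            f"{events.n_events} gated events < required minimum {min_cells}"
        )
    size = calib.size_at(median_channel(events, "FSC"))
    if not size > 0:
        raise CalibrationRangeError(
            f"median FSC maps to nonpositive size {size:.3g} um; outside calibration range"
        )
    return size


def chla_per_size(events: EventTable, size: float) -> float:
    """Median cellular Chl-a fluorescence divided by median cell size."""
    if not size > 0:
        raise InvalidInputError(f"size must be > 0, got {size}")
    return median_channel(events, "FL_RED") / size


def lipid_content(
    pre_stain: EventTable,
    post_stain: EventTable,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> float:
    """Neutral lipid per cell: post- minus pre-stain median green fluorescence.

    A negative delta is physically possible under noise and retained with a
    quality warning; clipping to zero would bias population comparisons.
    """
    for name, t in (("pre_stain", pre_stain), ("post_stain", post_stain)):
        if t.n_events < min_cells:
            raise InsufficientCellsError(f"{name}: {t.n_events} events < {min_cells}")
    delta = median_channel(post_stain, "FL_GREEN") - median_channel(pre_stain, "FL_GREEN")
    if delta < 0:
        warnings.warn(
            f"negative lipid stain delta ({delta:.3g}); retained unclipped",
            QualityWarning,
            stacklevel=2,
        )
    return delta


def silicification(
    stained_24h: EventTable,
    unstained_24h: EventTable,
    mu_24h: float,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> float:
    """PDMPO uptake per unit growth: UV stain delta divided by the 24-h rate.

    The unstained aliquot carries the background; the whole-population
    median absorbs occasional division-related double peaks.
    """
    if not mu_24h > 0:
        raise InvalidInputError(
            f"growth rate over the incubation must be > 0, got {mu_24h}; trait undefined"
        )
    for name, t in (("stained", stained_24h), ("unstained", unstained_24h)):
        if t.n_events < min_cells:
            raise InsufficientCellsError(f"{name}: {t.n_events} events < {min_cells}")
    delta = median_channel(stained_24h, "FL_UV") - median_channel(unstained_24h, "FL_UV")
    if delta < 0:
        warnings.warn(
            f"negative PDMPO stain delta ({delta:.3g}); retained unclipped",
            QualityWarning,
            stacklevel=2,
        )
    return delta / mu_24h


def cell_concentration(events: EventTable) -> float:
    """Cells per mL from gated event count and acquired volume (uL)."""
    v = events.acquired_volume_ul
    if not np.isfinite(v) or v <= 0:
        raise MissingMetadataError("acquired_volume_ul missing or nonpositive")
    return events.n_events / v * 1000.0


def bead_normalize(trait_value: float, qc_bead_median: float) -> float:
    """Standardise a fluorescence trait by the QC-bead median of its channel.

    Removes detector-gain differences so traits compare across experiments.
    """
    if not qc_bead_median > 0:
        raise InvalidInputError(f"qc_bead_median must be > 0, got {qc_bead_median}")
    return trait_value / qc_bead_median
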