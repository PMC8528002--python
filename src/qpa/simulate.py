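"""Synthetic instrument data with a recorded ground-truth manifest.

Every input stream of the assay is emulated with known truth so the full
pipeline is testable without deposited raw data: logistic growth curves
read as in vivo fluorescence, cytometry event clouds (population + debris
+ calibration beads), stain shifts (BODIPY green, PDMPO near-UV), rapid
light curves, and ROS plate readings.

Noise model choices: RFU noise is multiplicative lognormal (so log-linear
regression assumptions hold by construction); cytometry channels are
lognormal around the configured medians (fluorescence distributions are
right-skewed); debris is a separate low-signal lognormal component with
near-zero red fluorescence.  A single integer seed fixes all randomness
end-to-end, including per-well streams, via spawned seed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .core_io import (
    EventTable,
    FluorescenceSeries,
    PlateLayout,
    SampleMeta,
    TimeSeriesTable,
    WellAddress,
    PLATE_GEOMETRIES,
    write_events,
    write_fluorescence,
    write_layout,
    write_rlc,
)
from .cytometry import BeadCalibration, GateSpec
from .errors import InvalidInputError
from .photophys import DEFAULT_E_STEPS, RapidLightCurve, platt_etr

__all__ = [
    "StrainGroundTruth",
    "SimulationConfig",
    "SimulatedBundle",
    "DEFAULT_SIM_CALIBRATION",
    "DEBRIS_FSC_MEDIAN",
    "DEBRIS_FL_MEDIAN",
    "DEBRIS_SIGMA",
    "default_gate",
    "simulate_growth_series",
    "simulate_events",
    "simulate_bead_events",
    "simulate_stain_shift",
    "simulate_rlc",
    "simulate_ros_reading",
    "simulate_experiment",
    "default_strains",
]

#: Calibration used by the simulated instrument (counts per um; counts).
#: Positive intercept so the smallest bead (2 um) still scatters above zero.
DEFAULT_SIM_CALIBRATION = BeadCalibration(slope=20000.0, intercept=1000.0)

# Debris component: low forward scatter, essentially no chlorophyll signal.
DEBRIS_FSC_MEDIAN = 5000.0
DEBRIS_FL_MEDIAN = 20.0
DEBRIS_SIGMA = 0.5


def default_gate(quantile: float = 0.995) -> GateSpec:
    """Gate thresholds at the given quantile of the simulated debris cloud."""
    z = float(norm.ppf(quantile))
    return GateSpec(
        min_fl_red=DEBRIS_FL_MEDIAN * float(np.exp(z * DEBRIS_SIGMA)),
        min_fsc=DEBRIS_FSC_MEDIAN * float(np.exp(z * DEBRIS_SIGMA)),
    )


@dataclass(frozen=True)
class StrainGroundTruth:
    """True trait values of one simulated strain.

    ``ros_per_cell_true`` is in the trait's final units (counts per cell
    per um); the simulator multiplies back up by aliquot cell count and
    median size to produce the plate-reader RFU delta.  The implied true
    saturating irradiance is ``etrmax_true / alpha_true``.
    """

    mu_true: float  # d^-1
    carrying_capacity: float = 1e7  # RFU; high enough that an 8-day run stays exponential
    size_true: float = 6.0  # um equivalent spherical diameter
    ssc_median: float = 30000.0  # counts
    chla_median: float = 5000.0  # counts (red channel)
    lipid_delta_true: float = 250.0  # counts per cell (green channel)
    pdmpo_delta_true: float = 500.0  # counts per cell (UV channel)
    ros_per_cell_true: float = 0.5  # counts cell^-1 um^-1
    alpha_true: float = 0.3
    etrmax_true: float = 60.0
    beta_true: float = 0.0

    def __post_init__(self) -> None:
        if self.carrying_capacity <= 0 or self.size_true <= 0:
            raise InvalidInputError("carrying_capacity and size_true must be > 0")
        if self.alpha_true <= 0 or self.etrmax_true <= 0:
            raise InvalidInputError("alpha_true and etrmax_true must be > 0")
        if min(self.lipid_delta_true, self.pdmpo_delta_true, self.ros_per_cell_true,
               self.beta_true) < 0:
            raise InvalidInputError("deltas and beta_true must be >= 0")

    @property
    def ik_true(self) -> float:
        return self.etrmax_true / self.alpha_true

    @property
    def chla_per_size_true(self) -> float:
        return self.chla_median / self.size_true

    @property
    def silicification_true(self) -> float:
        # undefined without growth: the trait divides by the 24-h rate
        if self.mu_true <= 0:
            return float("nan")
        return self.pdmpo_delta_true / self.mu_true


def default_strains() -> dict[str, StrainGroundTruth]:
    """Six strains spanning the diatom trait ranges the assay targets."""
    return {
        "S1": StrainGroundTruth(mu_true=0.9, size_true=4.0, ssc_median=15000.0,
                                chla_median=3200.0, lipid_delta_true=150.0,
                                pdmpo_delta_true=300.0, ros_per_cell_true=0.4,
                                alpha_true=0.32, etrmax_true=70.0),
        "S2": StrainGroundTruth(mu_true=0.75, size_true=6.0, ssc_median=25000.0,
                                chla_median=5000.0, lipid_delta_true=220.0,
                                pdmpo_delta_true=450.0, ros_per_cell_true=0.5,
                                alpha_true=0.30, etrmax_true=62.0),
        "S3": StrainGroundTruth(mu_true=0.6, size_true=8.0, ssc_median=35000.0,
                                chla_median=6800.0, lipid_delta_true=300.0,
                                pdmpo_delta_true=600.0, ros_per_cell_true=0.55,
                                alpha_true=0.28, etrmax_true=55.0),
        "S4": StrainGroundTruth(mu_true=0.5, size_true=9.5, ssc_median=42000.0,
                                chla_median=8000.0, lipid_delta_true=380.0,
                                pdmpo_delta_true=750.0, ros_per_cell_true=0.6,
                                alpha_true=0.26, etrmax_true=50.0),
        "S5": StrainGroundTruth(mu_true=0.45, size_true=11.0, ssc_median=50000.0,
                                chla_median=9500.0, lipid_delta_true=450.0,
                                pdmpo_delta_true=900.0, ros_per_cell_true=0.7,
                                alpha_true=0.24, etrmax_true=45.0),
        "S6": StrainGroundTruth(mu_true=0.35, size_true=12.5, ssc_median=60000.0,
                                chla_median=11000.0, lipid_delta_true=520.0,
                                pdmpo_delta_true=1050.0, ros_per_cell_true=0.8,
                                alpha_true=0.22, etrmax_true=40.0),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment."""

    strains: Mapping[str, StrainGroundTruth] = field(default_factory=default_strains)
    n_replicates: int = 3
    days: int = 8
    f0: float = 100.0  # inoculation-day RFU
    noise_cv: float = 0.02  # lognormal CV of plate-reader RFU
    channel_sigma: float = 0.25  # lognormal shape of cytometry channels
    debris_fraction: float = 0.2
    events_per_acquisition: int = 5000
    cells_per_ml: float = 50000.0  # harvest-day density
    rlc_noise_sd_frac: float = 0.05  # additive ETR noise, fraction of ETRmax
    green_background: float = 200.0  # unstained green-channel median
    uv_background: float = 100.0  # unstained UV-channel median
    ros_blank_rfu: float = 500.0
    plate_format: int = 12
    vessel: str = "plate"
    environment_id: str = "f2_20C_60uE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if not self.strains:
            raise InvalidInputError("at least one strain is required")
        if self.days < 2:
            raise InvalidInputError("days must be >= 2")
        if not 0 <= self.debris_fraction < 1:
            raise InvalidInputError("debris_fraction must be in [0, 1)")
        if self.plate_format not in PLATE_GEOMETRIES:
            raise InvalidInputError(f"unsupported plate format {self.plate_format}")


# ---------------------------------------------------------------------------
# single-stream generators
# ---------------------------------------------------------------------------


def _lognorm_factor(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    """Multiplicative lognormal noise with median 1."""
    if sigma <= 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, sigma, n))


def simulate_growth_series(
    truth: StrainGroundTruth,
    f0: float,
    days: int,
    noise_cv: float,
    seed: int | np.random.SeedSequence,
) -> FluorescenceSeries:
    """Logistic mean curve with multiplicative lognormal RFU noise.

    F(t) = K f0 e^(mu t) / (K + f0 (e^(mu t) - 1)); early on (F << K) the
    log slope equals mu, so the log-linear estimator recovers the truth as
    noise vanishes.
    """
    if f0 <= 0:
        raise InvalidInputError("f0 must be > 0")
    if days < 2:
        raise InvalidInputError("days must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(days, dtype=float)
    k = truth.carrying_capacity
    growth = np.exp(truth.mu_true * t)
    mean = k * f0 * growth / (k + f0 * (growth - 1.0))
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    return FluorescenceSeries(times=t, rfu=mean * _lognorm_factor(rng, sigma, days))


def simulate_events(
    truth: StrainGroundTruth,
    calibration: BeadCalibration = DEFAULT_SIM_CALIBRATION,
    n_events: int = 5000,
    debris_fraction: float = 0.2,
    seed: int | np.random.SeedSequence = 0,
    channel_sigma: float = 0.25,
    green_background: float = 200.0,
    uv_background: float = 100.0,
    cells_per_ml: float = 50000.0,
) -> EventTable:
    """One cytometry acquisition: lognormal population cloud plus debris.

    The population median FSC sits on the calibration line at the strain's
    true size; the acquired volume is set so the population (not debris)
    corresponds to ``cells_per_ml``.
    """
    if n_events <= 0:
        raise InvalidInputError("n_events must be > 0")
    if not 0 <= debris_fraction < 1:
        raise InvalidInputError("debris_fraction must be in [0, 1)")
    fsc_med = calibration.fsc_at(truth.size_true)
    if fsc_med <= 0:
        raise InvalidInputError(
            f"size {truth.size_true} um maps to nonpositive FSC under this calibration"
        )
    rng = np.random.default_rng(seed)
    n_debris = int(round(n_events * debris_fraction))
    n_pop = n_events - n_debris

    def cloud(median: float, n: int, sigma: float) -> np.ndarray:
        return median * _lognorm_factor(rng, sigma, n)

    pop = {
        "fsc": cloud(fsc_med, n_pop, channel_sigma),
        "ssc": cloud(truth.ssc_median, n_pop, channel_sigma),
        "fl_red": cloud(truth.chla_median, n_pop, channel_sigma),
        "fl_green": cloud(green_background, n_pop, channel_sigma),
        "fl_uv": cloud(uv_background, n_pop, channel_sigma),
    }
    deb = {
        "fsc": cloud(DEBRIS_FSC_MEDIAN, n_debris, DEBRIS_SIGMA),
        "ssc": cloud(DEBRIS_FSC_MEDIAN / 2, n_debris, DEBRIS_SIGMA),
        "fl_red": cloud(DEBRIS_FL_MEDIAN, n_debris, DEBRIS_SIGMA),
        "fl_green": cloud(DEBRIS_FL_MEDIAN, n_debris, DEBRIS_SIGMA),
        "fl_uv": cloud(DEBRIS_FL_MEDIAN, n_debris, DEBRIS_SIGMA),
    }
    order = rng.permutation(n_events)
    merged = {k: np.concatenate([pop[k], deb[k]])[order] for k in pop}
    return EventTable(acquired_volume_ul=n_pop / cells_per_ml * 1000.0, **merged)


def simulate_bead_events(
    calibration: BeadCalibration = DEFAULT_SIM_CALIBRATION,
    diameters: tuple[float, ...] = (2.0, 4.0, 6.0, 10.0, 15.0),
    n_per_bead: int = 500,
    noise_sigma: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[EventTable, np.ndarray]:
    """Bead acquisition: one tight FSC cluster per known diameter.

    Returns the events and the per-event true diameter labels.
    """
    if len(set(diameters)) != len(diameters) or any(d <= 0 for d in diameters):
        raise InvalidInputError("diameters must be positive and distinct")
    rng = np.random.default_rng(seed)
    fsc, labels = [], []
    for d in diameters:
        centre = calibration.fsc_at(d)
        if centre <= 0:
            raise InvalidInputError(f"bead {d} um maps to nonpositive FSC")
        fsc.append(centre * _lognorm_factor(rng, noise_sigma, n_per_bead))
        labels.append(np.full(n_per_bead, d))
    n = n_per_bead * len(diameters)
    events = EventTable(
        fsc=np.concatenate(fsc),
        ssc=np.full(n, 1000.0),
        fl_red=np.zeros(n),
        fl_green=np.full(n, 5000.0),  # beads are bright in green: QC reference
        fl_uv=np.full(n, 5000.0),
        acquired_volume_ul=float("nan"),
    )
    return events, np.concatenate(labels)


def simulate_stain_shift(
    events: EventTable,
    channel: str,
    delta: float,
    seed: int | np.random.SeedSequence = 0,
    noise_sigma: float = 0.1,
) -> EventTable:
    """Post-stain acquisition: per-event uptake with median ``delta``.

    Uptake is delta x a median-1 lognormal factor, so the channel median
    shifts by delta (within sampling error) and other channels are
    untouched.  ``delta = 0`` returns the events unchanged.
    """
    if delta < 0:
        raise InvalidInputError("delta must be >= 0")
    if delta == 0:
        return events.subset(np.ones(events.n_events, dtype=bool))
    rng = np.random.default_rng(seed)
    uptake = delta * _lognorm_factor(rng, noise_sigma, events.n_events)
    return events.with_channel(channel, events.channel(channel) + uptake)


def simulate_rlc(
    truth: StrainGroundTruth,
    e_steps: tuple[float, ...] = DEFAULT_E_STEPS,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    etr_factor: float = 0.5,
    max_yield: float = 0.65,
) -> RapidLightCurve:
    """Rapid light curve with additive ETR noise, re-expressed as yields.

    Yields are back-computed as ETR / (etr_factor * E) for E > 0; the
    zero-irradiance step stores the maximal yield (the model's ETR there
    is zero regardless, so trait derivation never uses it).
    """
    e = np.asarray(e_steps, dtype=float)
    if e[0] != 0 or np.any(np.diff(e) <= 0):
        raise InvalidInputError("e_steps must be strictly increasing from 0")
    rng = np.random.default_rng(seed)
    if truth.beta_true > 0:
        # invert the ETRmax formula for the scale parameter
        ab = truth.alpha_true + truth.beta_true
        shape = (truth.alpha_true / ab) * (truth.beta_true / ab) ** (
            truth.beta_true / truth.alpha_true
        )
        ps = truth.etrmax_true / shape
    else:
        ps = truth.etrmax_true
    etr = platt_etr(e, truth.alpha_true, ps, truth.beta_true)
    if noise_sd > 0:
        etr = np.clip(etr + rng.normal(0.0, noise_sd, len(e)), 0.0, None)
    yields = np.empty_like(e)
    yields[0] = max_yield
    yields[1:] = np.clip(etr[1:] / (etr_factor * e[1:]), 0.0, 1.0)
    return RapidLightCurve(irradiance=e, yields=yields)


def simulate_ros_reading(
    truth: StrainGroundTruth,
    cells_in_aliquot: float,
    seed: int | np.random.SeedSequence = 0,
    blank_rfu: float = 500.0,
    noise_cv: float = 0.02,
) -> tuple[float, float]:
    """(stained_rfu, blank_rfu) of the ROS plate assay for one well."""
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    delta = truth.ros_per_cell_true * cells_in_aliquot * truth.size_true
    stained = blank_rfu + delta * float(_lognorm_factor(rng, sigma, 1)[0])
    blank = blank_rfu * float(_lognorm_factor(rng, sigma, 1)[0])
    return stained, blank


# ---------------------------------------------------------------------------
# whole-experiment bundles
# ---------------------------------------------------------------------------


@dataclass
class SimulatedBundle:
    """Paths and ground truth of one written fixture directory."""

    root: Path
    layout: PlateLayout
    manifest: pd.DataFrame  # one row per well: true trait values

    @property
    def layout_path(self) -> Path:
        return self.root / "layout.yaml"

    @property
    def fluorescence_path(self) -> Path:
        return self.root / "fluorescence.csv"

    @property
    def config_path(self) -> Path:
        return self.root / "config.yaml"


def _assign_wells(config: SimulationConfig) -> dict[WellAddress, tuple[str, SampleMeta]]:
    n_rows, n_cols = PLATE_GEOMETRIES[config.plate_format]
    per_plate = n_rows * n_cols
    wells: dict[WellAddress, tuple[str, SampleMeta]] = {}
    idx = 0
    for sid in sorted(config.strains):
        for rep in range(1, config.n_replicates + 1):
            plate = f"P{idx // per_plate + 1}"
            within = idx % per_plate
            addr = WellAddress(plate, "ABCDEFGH"[within // n_cols], within % n_cols + 1)
            wells[addr] = (
                sid,
                SampleMeta(
                    strain_id=sid,
                    environment_id=config.environment_id,
                    replicate=rep,
                    vessel=config.vessel,
                ),
            )
            idx += 1
    return wells


def simulate_experiment(config: SimulationConfig, out_dir: str | Path) -> SimulatedBundle:
    """Write a self-consistent fixture directory for one experiment.

    Contents: ``layout.yaml``, ``fluorescence.csv``, per-well event tables
    (pre-stain, BODIPY post-stain, PDMPO stained/unstained at 24 h), rapid
    light curves, ``ros.csv``, a ``manifest.csv`` of true trait values per
    well, and a ``config.yaml`` echoing every generation parameter.  Two
    runs with the same seed produce byte-identical bundles.
    """
    root = Path(out_dir)
    (root / "events").mkdir(parents=True, exist_ok=True)
    (root / "rlc").mkdir(exist_ok=True)

    assignment = _assign_wells(config)
    geometries = {a.plate_id: config.plate_format for a in assignment}
    layout = PlateLayout({a: m for a, (_, m) in assignment.items()}, geometries)
    write_layout(layout, root / "layout.yaml")

    ss = np.random.SeedSequence(config.seed)
    streams_per_well = 7
    children = ss.spawn(len(assignment) * streams_per_well)

    series: dict[WellAddress, FluorescenceSeries] = {}
    ros_rows: list[str] = []
    manifest_rows: list[dict] = []
    for i, addr in enumerate(sorted(assignment)):
        sid, _ = assignment[addr]
        truth = config.strains[sid]
        seeds = children[i * streams_per_well : (i + 1) * streams_per_well]

        series[addr] = simulate_growth_series(
            truth, config.f0, config.days, config.noise_cv, seeds[0]
        )

        ev_kwargs = dict(
            calibration=DEFAULT_SIM_CALIBRATION,
            n_events=config.events_per_acquisition,
            debris_fraction=config.debris_fraction,
            channel_sigma=config.channel_sigma,
            green_background=config.green_background,
            uv_background=config.uv_background,
            cells_per_ml=config.cells_per_ml,
        )
        prestain = simulate_events(truth, seed=seeds[1], **ev_kwargs)
        bodipy = simulate_stain_shift(
            prestain, "FL_GREEN", truth.lipid_delta_true, seed=seeds[2]
        )
        pdmpo_unstained = simulate_events(truth, seed=seeds[3], **ev_kwargs)
        pdmpo_stained = simulate_stain_shift(
            pdmpo_unstained, "FL_UV", truth.pdmpo_delta_true, seed=seeds[4]
        )
        tag = f"{addr.plate_id}_{addr.label}"
        write_events(prestain, root / "events" / f"{tag}_prestain.csv")
        write_events(bodipy, root / "events" / f"{tag}_bodipy.csv")
        write_events(pdmpo_unstained, root / "events" / f"{tag}_pdmpo_unstained.csv")
        write_events(pdmpo_stained, root / "events" / f"{tag}_pdmpo_stained.csv")

        curve = simulate_rlc(
            truth, noise_sd=config.rlc_noise_sd_frac * truth.etrmax_true, seed=seeds[5]
        )
        write_rlc(curve, root / "rlc" / f"{tag}.csv")

        cells_aliquot = config.cells_per_ml * 0.5  # 500 uL aliquot
        stained, blank = simulate_ros_reading(
            truth, cells_aliquot, seed=seeds[6], blank_rfu=config.ros_blank_rfu,
            noise_cv=config.noise_cv,
        )
        ros_rows.append(f"{addr.key},{stained!r},{blank!r},500.0")

        manifest_rows.append(
            {
                "well": addr.key,
                "strain_id": sid,
                "growth_rate": truth.mu_true,
                "size": truth.size_true,
                "granularity": truth.ssc_median,
                "chla_per_size": truth.chla_per_size_true,
                "lipid": truth.lipid_delta_true,
                "silicification": truth.silicification_true,
                "ros": truth.ros_per_cell_true,
                "alpha": truth.alpha_true,
                "ik": truth.ik_true,
                "etrmax": truth.etrmax_true,
            }
        )

    write_fluorescence(TimeSeriesTable(series), root / "fluorescence.csv")
    with open(root / "ros.csv", "w") as fh:
        fh.write("well,stained_rfu,blank_rfu,aliquot_volume_ul\n")
        fh.write("\n".join(ros_rows) + "\n")

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(root / "manifest.csv", index=False)

    gate = default_gate()
    echo = {
        "simulation": {
            "n_replicates": config.n_replicates,
            "days": config.days,
            "f0": config.f0,
            "noise_cv": config.noise_cv,
            "channel_sigma": config.channel_sigma,
            "debris_fraction": config.debris_fraction,
            "events_per_acquisition": config.events_per_acquisition,
            "cells_per_ml": config.cells_per_ml,
            "rlc_noise_sd_frac": config.rlc_noise_sd_frac,
            "plate_format": config.plate_format,
            "seed": config.seed,
            "strains": {
                sid: {k: getattr(t, k) for k in (
                    "mu_true", "carrying_capacity", "size_true", "ssc_median",
                    "chla_median", "lipid_delta_true", "pdmpo_delta_true",
                    "ros_per_cell_true", "alpha_true", "etrmax_true", "beta_true")}
                for sid, t in sorted(config.strains.items())
            },
        },
        "analysis": {
            "calibration": {
                "slope": DEFAULT_SIM_CALIBRATION.slope,
                "intercept": DEFAULT_SIM_CALIBRATION.intercept,
            },
            "gate": {"min_fl_red": gate.min_fl_red, "min_fsc": gate.min_fsc},
            "min_cells": 200,
            "growth_window": 4,
        },
    }
    (root / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    return SimulatedBundle(root=root, layout=layout, manifest=manifest)
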