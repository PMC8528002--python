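"""ROS trait derivation and assembly of the per-well trait table.

Also hosts :func:`process_bundle`, the end-to-end pipeline that turns a
fixture/experiment directory (layout + instrument files) into the tidy
wells x traits table consumed by the ordination and permutation-test
modules.  Wells whose cultures did not grow are excluded with a logged
reason rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cytometry, growth, photophys
from .core_io import (
    META_COLUMNS,
    TRAIT_COLUMNS,
    PlateLayout,
    TraitTable,
    WellAddress,
    read_events,
    read_fluorescence,
    read_layout,
    read_rlc,
)
from .cytometry import BeadCalibration, GateSpec
from .errors import (
    InvalidInputError,
    QPAError,
    QualityWarning,
    ReconciliationError,
)

__all__ = ["RosReading", "TraitRecord", "ros_per_cell_per_size", "assemble_trait_table",
           "process_bundle"]


@dataclass(frozen=True)
class RosReading:
    """Plate-reader fluorescence of the stained and blank (unstained) aliquots."""

    stained_rfu: float
    blank_rfu: float
    aliquot_volume_ul: float = 500.0

    def __post_init__(self) -> None:
        if self.stained_rfu < 0 or self.blank_rfu < 0:
            raise InvalidInputError("RFU readings must be >= 0")
        if not self.aliquot_volume_ul > 0:
            raise InvalidInputError("aliquot_volume_ul must be > 0")


def ros_per_cell_per_size(
    reading: RosReading, cells_per_ml: float, median_size: float
) -> float:
    """ROS per cell per um: stain delta over aliquot cell count over size.

    delta RFU / (cells in the aliquot) / (median cell size, um).  A
    negative delta (blank brighter than stained) is retained with a
    quality warning rather than clipped.
    """
    if not cells_per_ml > 0:
        raise InvalidInputError("cells_per_ml must be > 0; trait undefined without cells")
    if not median_size > 0:
        raise InvalidInputError("median_size must be > 0")
    delta = reading.stained_rfu - reading.blank_rfu
    if delta < 0:
        warnings.warn(
            f"negative ROS delta ({delta:.3g}); retained unclipped",
            QualityWarning,
            stacklevel=2,
        )
    cells_in_aliquot = cells_per_ml * reading.aliquot_volume_ul / 1000.0
    return delta / cells_in_aliquot / median_size


@dataclass(frozen=True)
class TraitRecord:
    """One derived trait value for one well, with its provenance."""

    well: WellAddress
    trait: str
    value: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_COLUMNS:
            raise InvalidInputError(f"unknown trait {self.trait!r}")


def assemble_trait_table(
    layout: PlateLayout,
    records: Iterable[TraitRecord],
    exclude: Mapping[WellAddress, str] | None = None,
) -> TraitTable:
    """One row per layout well (minus exclusions), fixed trait column order.

    Raises :class:`ReconciliationError` for records whose well is not in
    the layout (orphans) or for duplicate (well, trait) results.  Traits
    never measured for a well stay NaN — explicitly missing, never zero.
    """
    exclude = dict(exclude or {})
    values: dict[WellAddress, dict[str, float]] = {}
    prov_rows = []
    orphans, dupes = [], []
    for rec in records:
        if rec.well not in layout.wells:
            orphans.append(rec.well.key)
            continue
        slot = values.setdefault(rec.well, {})
        if rec.trait in slot:
            dupes.append((rec.well.key, rec.trait))
            continue
        slot[rec.trait] = rec.value
        prov_rows.append((rec.well.key, rec.trait, rec.source))
    if orphans:
        raise ReconciliationError(f"results for wells absent from layout: {sorted(set(orphans))}")
    if dupes:
        raise ReconciliationError(f"duplicate results for (well, trait): {sorted(set(dupes))}")

    rows = []
    for addr in sorted(layout.wells):
        if addr in exclude:
            continue
        meta = layout.wells[addr]
        row = {
            "plate_id": addr.plate_id,
            "row": addr.row,
            "column": addr.column,
            "strain_id": meta.strain_id,
            "environment_id": meta.environment_id,
            "replicate": meta.replicate,
            "vessel": meta.vessel,
        }
        for trait in TRAIT_COLUMNS:
            row[trait] = values.get(addr, {}).get(trait, np.nan)
        rows.append(row)
    data = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(TRAIT_COLUMNS))
    provenance = pd.DataFrame(prov_rows, columns=["well", "trait", "source"])
    return TraitTable(data=data, provenance=provenance)


def process_bundle(
    bundle_dir: str | Path,
) -> tuple[TraitTable, dict[WellAddress, str]]:
    """Run the full assay pipeline on an experiment directory.

    Reads the bundle's ``config.yaml`` for the calibration, gate and
    analysis parameters, derives all ten traits per well, and returns the
    trait table together with the excluded wells (no growth) and reasons.
    Individual trait failures leave that cell missing; they never abort
    the well.
    """
    root = Path(bundle_dir)
    cfg = yaml.safe_load((root / "config.yaml").read_text())["analysis"]
    calib = BeadCalibration(
        slope=float(cfg["calibration"]["slope"]),
        intercept=float(cfg["calibration"]["intercept"]),
    )
    gate = GateSpec(
        min_fl_red=float(cfg["gate"]["min_fl_red"]),
        min_fsc=float(cfg["gate"]["min_fsc"]),
    )
    min_cells = int(cfg.get("min_cells", 200))
    window = int(cfg.get("growth_window", 4))
    # "no increase over time": slopes within plate-reader noise of zero
    no_growth_mu = float(cfg.get("no_growth_mu", 0.05))

    layout = read_layout(root / "layout.yaml")
    fluor = read_fluorescence(root / "fluorescence.csv")
    ros_df = pd.read_csv(root / "ros.csv").set_index("well")

    records: list[TraitRecord] = []
    exclusions: dict[WellAddress, str] = {}
    for addr in layout:
        series = fluor[addr]
        fit = growth.max_growth_rate(series, window_size=window)
        if fit.mu <= no_growth_mu:
            exclusions[addr] = f"no growth (max log-slope {fit.mu:.3g} d^-1)"
            continue
        records.append(TraitRecord(addr, "growth_rate", fit.mu, "fluorescence.csv"))

        tag = f"{addr.plate_id}_{addr.label}"
        try:
            prestain = gate_and_read(root, f"{tag}_prestain.csv", gate)
            size = cytometry.estimate_size(calib, prestain, min_cells=min_cells)
            records.append(TraitRecord(addr, "size", size, f"{tag}_prestain.csv"))
            records.append(
                TraitRecord(addr, "granularity",
                            cytometry.median_channel(prestain, "SSC"),
                            f"{tag}_prestain.csv")
            )
            records.append(
                TraitRecord(addr, "chla_per_size",
                            cytometry.chla_per_size(prestain, size),
                            f"{tag}_prestain.csv")
            )
        except QPAError:
            prestain, size = None, None

        if prestain is not None:
            try:
                post = gate_and_read(root, f"{tag}_bodipy.csv", gate)
                records.append(
                    TraitRecord(addr, "lipid",
                                cytometry.lipid_content(prestain, post, min_cells=min_cells),
                                f"{tag}_bodipy.csv")
                )
            except QPAError:
                pass

        try:
            unstained = gate_and_read(root, f"{tag}_pdmpo_unstained.csv", gate)
            stained = gate_and_read(root, f"{tag}_pdmpo_stained.csv", gate)
            mu24 = growth.growth_over_interval(
                series, series.times[-1] - 1.0, series.times[-1]
            )
            records.append(
                TraitRecord(addr, "silicification",
                            cytometry.silicification(stained, unstained, mu24,
                                                     min_cells=min_cells),
                            f"{tag}_pdmpo_stained.csv")
            )
        except QPAError:
            pass

        if prestain is not None and size is not None and addr.key in ros_df.index:
            r = ros_df.loc[addr.key]
            try:
                conc = cytometry.cell_concentration(prestain)
                reading = RosReading(
                    stained_rfu=float(r.stained_rfu),
                    blank_rfu=float(r.blank_rfu),
                    aliquot_volume_ul=float(r.aliquot_volume_ul),
                )
                records.append(
                    TraitRecord(addr, "ros",
                                ros_per_cell_per_size(reading, conc, size), "ros.csv")
                )
            except QPAError:
                pass

        rlc_path = root / "rlc" / f"{tag}.csv"
        if rlc_path.exists():
            try:
                curve = read_rlc(rlc_path)
                fit_pi = photophys.fit_rlc(curve)
                for trait, value in (
                    ("alpha", fit_pi.alpha), ("ik", fit_pi.ik), ("etrmax", fit_pi.etrmax)
                ):
                    records.append(TraitRecord(addr, trait, value, rlc_path.name))
            except QPAError:
                pass

    return assemble_trait_table(layout, records, exclude=exclusions), exclusions


def gate_and_read(root: Path, name: str, gate: GateSpec):
    """Read one delimited event table from the bundle and apply the cell gate."""
    return cytometry.gate_events(read_events(root / "events" / name), gate)
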