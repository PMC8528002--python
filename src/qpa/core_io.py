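"""Domain types, plate-layout and instrument-file I/O, protocol arithmetic.

The assay phenotypes microalgae grown in multi-well plates.  Every other
module consumes the containers defined here: a :class:`PlateLayout` mapping
wells to sample metadata, per-well fluorescence :class:`TimeSeriesTable`
for growth estimation, per-event cytometry :class:`EventTable`, and the
final wells x traits :class:`TraitTable`.

All file formats are plain delimited text (or YAML for layout/config) so
that fixtures can be generated and inspected without binary tooling.
Cytometer exports are per-event channel tables; instrument-specific column
names are translated to the canonical channel set via a config-level map.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ChannelMappingError, InvalidInputError, ParseError

__all__ = [
    "PLATE_GEOMETRIES",
    "CHANNELS",
    "TRAIT_UNITS",
    "TRAIT_COLUMNS",
    "WellAddress",
    "SampleMeta",
    "PlateLayout",
    "FluorescenceSeries",
    "TimeSeriesTable",
    "EventTable",
    "TraitTable",
    "nominal_final_concentration",
    "dilution_final_concentration",
    "total_inoculum",
    "read_layout",
    "write_layout",
    "read_fluorescence",
    "write_fluorescence",
    "read_events",
    "write_events",
    "read_rlc",
    "write_rlc",
    "read_trait_table",
    "write_trait_table",
]

#: Supported plate formats: wells -> (n_rows, n_columns).
PLATE_GEOMETRIES: dict[int, tuple[int, int]] = {12: (3, 4), 24: (4, 6), 48: (6, 8)}

#: Canonical cytometer channel names used throughout the package.
CHANNELS: tuple[str, ...] = ("FSC", "SSC", "FL_RED", "FL_GREEN", "FL_UV")

#: Trait column order and units of the tidy trait table.
TRAIT_UNITS: dict[str, str] = {
    "growth_rate": "d-1",
    "size": "um",
    "granularity": "counts",
    "chla_per_size": "counts um-1",
    "lipid": "counts cell-1",
    "silicification": "counts d",
    "ros": "counts cell-1 um-1",
    "alpha": "dimensionless",
    "ik": "umol m-2 s-1",
    "etrmax": "rel units",
}
TRAIT_COLUMNS: tuple[str, ...] = tuple(TRAIT_UNITS)

META_COLUMNS: tuple[str, ...] = (
    "plate_id",
    "row",
    "column",
    "strain_id",
    "environment_id",
    "replicate",
    "vessel",
)

_ROW_LETTERS = "ABCDEFGH"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class WellAddress:
    """One well of a named plate, e.g. ``P1/A1``."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if len(self.row) != 1 or self.row not in _ROW_LETTERS:
            raise InvalidInputError(f"row must be a single letter A-H, got {self.row!r}")
        if self.column < 1:
            raise InvalidInputError(f"column must be >= 1, got {self.column}")

    @property
    def label(self) -> str:
        return f"{self.row}{self.column}"

    @property
    def key(self) -> str:
        return f"{self.plate_id}/{self.label}"

    @classmethod
    def from_key(cls, key: str) -> "WellAddress":
        plate_id, _, label = key.rpartition("/")
        m = re.fullmatch(r"([A-H])(\d+)", label)
        if not plate_id or m is None:
            raise ParseError(f"malformed well key {key!r} (expected e.g. 'P1/A1')")
        return cls(plate_id, m.group(1), int(m.group(2)))

    def in_geometry(self, n_wells: int) -> bool:
        if n_wells not in PLATE_GEOMETRIES:
            raise InvalidInputError(f"unsupported plate format: {n_wells} wells")
        n_rows, n_cols = PLATE_GEOMETRIES[n_wells]
        return _ROW_LETTERS.index(self.row) < n_rows and self.column <= n_cols


@dataclass(frozen=True)
class SampleMeta:
    """What was grown in a well: strain, environment, replicate, vessel."""

    strain_id: str
    environment_id: str
    replicate: int
    vessel: str = "plate"
    volume_ml: float = 4.4
    temperature_c: float = 20.0
    irradiance: float = 60.0

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise InvalidInputError("replicate must be a positive integer")
        if self.vessel not in ("plate", "flask"):
            raise InvalidInputError(f"vessel must be 'plate' or 'flask', got {self.vessel!r}")
        if self.volume_ml <= 0:
            raise InvalidInputError("volume_ml must be > 0")
        if self.irradiance < 0:
            raise InvalidInputError("irradiance must be >= 0")


class PlateLayout:
    """Mapping of well addresses to sample metadata, with plate geometries.

    Invariants enforced at construction: every address fits its plate's
    declared geometry, and replicate numbers are unique within each
    (strain, environment, vessel) combination.
    """

    def __init__(
        self,
        wells: Mapping[WellAddress, SampleMeta],
        geometries: Mapping[str, int],
    ) -> None:
        self.wells = dict(wells)
        self.geometries = dict(geometries)
        seen: set[tuple[str, str, str, int]] = set()
        for addr, meta in self.wells.items():
            if addr.plate_id not in self.geometries:
                raise InvalidInputError(f"plate {addr.plate_id!r} has no declared geometry")
            if not addr.in_geometry(self.geometries[addr.plate_id]):
                raise InvalidInputError(
                    f"well {addr.key} outside the {self.geometries[addr.plate_id]}-well format"
                )
            k = (meta.strain_id, meta.environment_id, meta.vessel, meta.replicate)
            if k in seen:
                raise InvalidInputError(
                    f"duplicate replicate {meta.replicate} for "
                    f"({meta.strain_id}, {meta.environment_id}, {meta.vessel})"
                )
            seen.add(k)

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self):
        return iter(sorted(self.wells))

    def __getitem__(self, addr: WellAddress) -> SampleMeta:
        return self.wells[addr]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PlateLayout)
            and self.wells == other.wells
            and self.geometries == other.geometries
        )


@dataclass
class FluorescenceSeries:
    """Daily in vivo Chl-a readings of one well: biomass proxy for growth."""

    times: np.ndarray  # days, strictly increasing
    rfu: np.ndarray  # relative fluorescence units, > 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.times.shape != self.rfu.shape or self.times.ndim != 1:
            raise InvalidInputError("times and rfu must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise InvalidInputError("times must be nonnegative")
        if np.any(self.rfu <= 0) or not np.all(np.isfinite(self.rfu)):
            raise InvalidInputError("rfu values must be positive and finite")

    def __len__(self) -> int:
        return len(self.times)


class TimeSeriesTable:
    """Per-well fluorescence series for a whole experiment."""

    def __init__(self, series: Mapping[WellAddress, FluorescenceSeries]) -> None:
        self.series = dict(series)

    def __len__(self) -> int:
        return len(self.series)

    def __getitem__(self, addr: WellAddress) -> FluorescenceSeries:
        return self.series[addr]

    def __iter__(self):
        return iter(sorted(self.series))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSeriesTable) or set(self.series) != set(other.series):
            return False
        return all(
            np.array_equal(self.series[a].times, other.series[a].times)
            and np.array_equal(self.series[a].rfu, other.series[a].rfu)
            for a in self.series
        )


@dataclass
class EventTable:
    """Per-cell scatter/fluorescence values from one cytometry acquisition.

    Channels carry raw instrument counts; ``acquired_volume_ul`` is the
    sample volume analysed, needed to convert event counts to cells/mL.
    """

    fsc: np.ndarray
    ssc: np.ndarray
    fl_red: np.ndarray
    fl_green: np.ndarray
    fl_uv: np.ndarray
    acquired_volume_ul: float = float("nan")

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in CHANNELS:
            a = np.asarray(getattr(self, name.lower()), dtype=float)
            if a.ndim != 1:
                raise InvalidInputError(f"channel {name} must be a 1-D array")
            if n is None:
                n = len(a)
            elif len(a) != n:
                raise InvalidInputError("all channel vectors must have equal length")
            if np.any(a < 0):
                raise InvalidInputError(f"channel {name} has negative counts")
            arrays[name.lower()] = a
        for k, v in arrays.items():
            setattr(self, k, v)

    @property
    def n_events(self) -> int:
        return len(self.fsc)

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise InvalidInputError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name.lower())

    def subset(self, mask: np.ndarray) -> "EventTable":
        return EventTable(
            fsc=self.fsc[mask],
            ssc=self.ssc[mask],
            fl_red=self.fl_red[mask],
            fl_green=self.fl_green[mask],
            fl_uv=self.fl_uv[mask],
            acquired_volume_ul=self.acquired_volume_ul,
        )

    def with_channel(self, name: str, values: np.ndarray) -> "EventTable":
        return replace(self, **{name.lower(): np.asarray(values, dtype=float)})


@dataclass
class TraitTable:
    """Tidy wells x traits table: one row per well, fixed trait columns.

    ``data`` holds the metadata columns followed by the ten trait columns
    in canonical order; missing trait values are NaN, never silent zeros.
    ``provenance`` optionally records (well, trait, source) rows.
    """

    data: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"trait table missing metadata columns {missing}")
        cols = [c for c in self.data.columns if c not in META_COLUMNS]
        unknown = [c for c in cols if c not in TRAIT_UNITS]
        if unknown:
            raise InvalidInputError(f"unknown trait columns {unknown}")
        ordered = list(META_COLUMNS) + [c for c in TRAIT_COLUMNS if c in cols]
        self.data = self.data[ordered].reset_index(drop=True)

    @property
    def trait_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in TRAIT_UNITS]

    def trait_matrix(self, complete_only: bool = True) -> pd.DataFrame:
        """Trait values indexed by well key; optionally complete cases only."""
        keys = [
            WellAddress(p, r, int(c)).key
            for p, r, c in zip(self.data.plate_id, self.data.row, self.data.column)
        ]
        m = self.data[self.trait_columns].copy()
        m.index = pd.Index(keys, name="well")
        if complete_only:
            m = m.dropna(axis=0, how="any")
        return m

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitTable):
            return False
        try:
            pd.testing.assert_frame_equal(self.data, other.data)
        except AssertionError:
            return False
        return True


# ---------------------------------------------------------------------------
# protocol arithmetic
# ---------------------------------------------------------------------------


def nominal_final_concentration(
    stock_conc: float, added_volume: float, sample_volume: float
) -> float:
    """Nominal final concentration after adding stain stock to a sample.

    The denominator is the sample volume, not sample + stain: adding 5 uL
    of 12.5 uM stock to a 500 uL aliquot is reported as 0.125 uM.  This is
    the convention of bench protocols, where the stain volume is negligible.
    """
    for name, v in (("stock_conc", stock_conc), ("added_volume", added_volume),
                    ("sample_volume", sample_volume)):
        if not v > 0:
            raise InvalidInputError(f"{name} must be > 0, got {v}")
    return stock_conc * added_volume / sample_volume


def dilution_final_concentration(stock_conc: float, dilution_factor: float) -> float:
    """Concentration after a 1/``dilution_factor`` dilution of a stock."""
    if not stock_conc > 0:
        raise InvalidInputError(f"stock_conc must be > 0, got {stock_conc}")
    if not dilution_factor >= 1:
        raise InvalidInputError(f"dilution_factor must be >= 1, got {dilution_factor}")
    return stock_conc / dilution_factor


def total_inoculum(cells_per_ml: float, well_volume_ml: float, n_wells: int) -> float:
    """Total cells needed to inoculate ``n_wells`` wells at a target density."""
    if not cells_per_ml > 0:
        raise InvalidInputError("cells_per_ml must be > 0")
    if not well_volume_ml > 0:
        raise InvalidInputError("well_volume_ml must be > 0")
    if not n_wells > 0:
        raise InvalidInputError("n_wells must be a positive integer")
    return cells_per_ml * well_volume_ml * n_wells


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    doc: dict = {"plates": {}}
    for pid in sorted(layout.geometries):
        doc["plates"][pid] = {"geometry": layout.geometries[pid], "wells": {}}
    for addr in sorted(layout.wells):
        meta = layout.wells[addr]
        doc["plates"][addr.plate_id]["wells"][addr.label] = {
            "strain_id": meta.strain_id,
            "environment_id": meta.environment_id,
            "replicate": meta.replicate,
            "vessel": meta.vessel,
            "volume_ml": meta.volume_ml,
            "temperature_c": meta.temperature_c,
            "irradiance": meta.irradiance,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_layout(path: str | Path) -> PlateLayout:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:  # pragma: no cover - yaml error text varies
        raise ParseError(f"{path}: invalid YAML: {e}") from e
    if not isinstance(doc, dict) or "plates" not in doc:
        raise ParseError(f"{path}: missing top-level 'plates' mapping")
    wells: dict[WellAddress, SampleMeta] = {}
    geometries: dict[str, int] = {}
    for pid, pdoc in doc["plates"].items():
        if "geometry" not in pdoc:
            raise ParseError(f"{path}: plate {pid!r} missing 'geometry'")
        geometries[pid] = int(pdoc["geometry"])
        for label, w in (pdoc.get("wells") or {}).items():
            addr = WellAddress.from_key(f"{pid}/{label}")
            try:
                wells[addr] = SampleMeta(
                    strain_id=str(w["strain_id"]),
                    environment_id=str(w["environment_id"]),
                    replicate=int(w["replicate"]),
                    vessel=str(w.get("vessel", "plate")),
                    volume_ml=float(w.get("volume_ml", 4.4)),
                    temperature_c=float(w.get("temperature_c", 20.0)),
                    irradiance=float(w.get("irradiance", 60.0)),
                )
            except KeyError as e:
                raise ParseError(f"{path}: well {pid}/{label} missing keyword {e}") from e
    return PlateLayout(wells, geometries)


def write_fluorescence(table: TimeSeriesTable, path: str | Path) -> None:
    rows = []
    for addr in sorted(table.series):
        s = table.series[addr]
        for t, f in zip(s.times, s.rfu):
            rows.append((addr.key, repr(float(t)), repr(float(f))))
    with open(path, "w") as fh:
        fh.write("well,time_days,rfu\n")
        for r in rows:
            fh.write(",".join(r) + "\n")


def read_fluorescence(path: str | Path) -> TimeSeriesTable:
    try:
        df = pd.read_csv(path, dtype={"well": str}, float_precision="round_trip")
    except Exception as e:
        raise ParseError(f"{path}: cannot parse delimited fluorescence table: {e}") from e
    for col in ("well", "time_days", "rfu"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    series: dict[WellAddress, FluorescenceSeries] = {}
    for key, g in df.groupby("well", sort=True):
        addr = WellAddress.from_key(str(key))
        g = g.sort_values("time_days")
        series[addr] = FluorescenceSeries(g.time_days.to_numpy(), g.rfu.to_numpy())
    return TimeSeriesTable(series)


def write_events(events: EventTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        if math.isfinite(events.acquired_volume_ul):
            fh.write(f"# acquired_volume_ul={events.acquired_volume_ul!r}\n")
        fh.write(",".join(CHANNELS) + "\n")
        cols = [events.channel(c) for c in CHANNELS]
        for row in zip(*cols):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_events(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    required: Iterable[str] = CHANNELS,
) -> EventTable:
    """Read a delimited per-event channel table.

    ``channel_map`` translates instrument column headers (e.g. filter names
    like ``488-690/50``) to the canonical channel set; identity is assumed
    for columns already canonically named.  A required channel that cannot
    be resolved raises :class:`ChannelMappingError`.
    """
    volume = float("nan")
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            m = re.match(r"#\s*acquired_volume_ul\s*=\s*(\S+)", first)
            if m:
                volume = float(m.group(1))
            first = fh.readline()
        header = [h.strip() for h in first.rstrip("\n").split(",")]
        try:
            df = pd.read_csv(fh, names=header, float_precision="round_trip")
        except Exception as e:
            raise ParseError(f"{path}: cannot parse event table: {e}") from e
    rename = {alias: canon for alias, canon in (channel_map or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ChannelMappingError(
            f"{path}: cannot resolve required channel(s) {missing}; "
            f"columns present: {list(df.columns)}"
        )
    kwargs = {c.lower(): df[c].to_numpy(dtype=float) for c in CHANNELS if c in df.columns}
    for c in CHANNELS:
        kwargs.setdefault(c.lower(), np.zeros(len(df)))
    return EventTable(acquired_volume_ul=volume, **kwargs)


def write_rlc(curve, path: str | Path) -> None:
    """Write a rapid-light-curve export (step, irradiance, yield, flag)."""
    with open(path, "w") as fh:
        fh.write(f"# dilution_fraction={curve.dilution_fraction!r}\n")
        fh.write("step,irradiance,yield,saturated\n")
        for i, (e, y, s) in enumerate(
            zip(curve.irradiance, curve.yields, curve.saturated), start=1
        ):
            fh.write(f"{i},{float(e)!r},{float(y)!r},{int(s)}\n")


def read_rlc(path: str | Path):
    from .photophys import RapidLightCurve

    dilution = 0.50
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            m = re.match(r"#\s*dilution_fraction\s*=\s*(\S+)", first)
            if m:
                dilution = float(m.group(1))
            first = fh.readline()
        header = [h.strip() for h in first.rstrip("\n").split(",")]
        try:
            df = pd.read_csv(fh, names=header, float_precision="round_trip")
        except Exception as e:
            raise ParseError(f"{path}: cannot parse light-curve table: {e}") from e
    for col in ("irradiance", "yield", "saturated"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    df = df.sort_values("irradiance")
    return RapidLightCurve(
        irradiance=df["irradiance"].to_numpy(dtype=float),
        yields=df["yield"].to_numpy(dtype=float),
        saturated=df["saturated"].to_numpy(dtype=bool),
        dilution_fraction=dilution,
    )


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Tidy delimited text with a units comment line above the data."""
    units = ";".join(f"{c}={TRAIT_UNITS[c]}" for c in table.trait_columns)
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        table.data.to_csv(fh, index=False)


def read_trait_table(path: str | Path) -> TraitTable:
    try:
        df = pd.read_csv(
            path, comment="#", dtype={"plate_id": str, "row": str},
            float_precision="round_trip",
        )
    except Exception as e:
        raise ParseError(f"{path}: cannot parse trait table: {e}") from e
    return TraitTable(df)
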