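"""Point measurement tables: the 13-column field data schema.

Each record is one field point on or around the plateau: position, elevation,
meteorology, measured oxygen concentration (percent by volume at ~1.5 m above
ground), optional fractional vegetation coverage (FVC) and map-derived
geomorphologic/vegetation labels, plus the instrument group (A-D) the reading
came from.  Tables are read and written as UTF-8 CSV or as spreadsheet
workbooks; "/" and empty cells both denote an absent optional value, matching
the published table convention.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .errors import RowParseError, SchemaError

#: Instrument groups in service by year: the CY-12C meters (A) in 2017, the
#: first TD400 set (B) 2018-2020, the replacement set (C) in 2021 and the
#: newly purchased set (D) in 2022.
GROUP_BY_YEAR = {2017: "A", 2018: "B", 2019: "B", 2020: "B", 2021: "C", 2022: "D"}
INSTRUMENT_GROUPS = ("A", "B", "C", "D")

#: Geographic extent of the study-area rasters (decimal degrees, WGS-84).
PLATEAU_WEST, PLATEAU_EAST = 73.50, 104.67
PLATEAU_SOUTH, PLATEAU_NORTH = 26.05, 39.91

# Published column headers, in table order.
COLUMNS = [
    "TID",
    "FID",
    "Time",
    "Longitude (°)",
    "Latitude (°)",
    "Elevation (m)",
    "Temperature (°C)",
    "Relative humidity (%)",
    "Atmospheric pressure (hpa)",
    "Oxygen concentration (%)",
    "FVC (%)",
    "Geomorphologic type",
    "Vegetation type",
]

_FIELD_BY_KEY = {
    "tid": "tid",
    "fid": "fid",
    "time": "timestamp",
    "longitude": "longitude",
    "latitude": "latitude",
    "elevation": "elevation",
    "temperature": "temperature",
    "relative humidity": "relative_humidity",
    "atmospheric pressure": "pressure",
    "oxygen concentration": "oxygen_concentration",
    "fvc": "fvc",
    "geomorphologic type": "geomorph_type",
    "vegetation type": "vegetation_type",
    "instrument group": "instrument_group",
}
_MANDATORY = ("longitude", "latitude", "elevation", "oxygen_concentration")
_NUMERIC = (
    "longitude",
    "latitude",
    "elevation",
    "temperature",
    "relative_humidity",
    "pressure",
    "oxygen_concentration",
    "fvc",
)
_TIME_FORMATS = ("%Y/%m/%d %H:%M", "%Y/%m/%d %H:%M:%S", "%Y/%m/%d")


@dataclass
class MeasurementRecord:
    """One field measurement point (one row of the 13-column table)."""

    tid: Optional[str] = None
    fid: Optional[str] = None
    timestamp: Optional[datetime] = None
    longitude: Optional[float] = None
    latitude: Optional[float] = None
    elevation: Optional[float] = None
    temperature: Optional[float] = None
    relative_humidity: Optional[float] = None
    pressure: Optional[float] = None
    oxygen_concentration: Optional[float] = None
    fvc: Optional[float] = None
    geomorph_type: Optional[str] = None
    vegetation_type: Optional[str] = None
    instrument_group: Optional[str] = None
    #: In-memory provenance note set by calibration; never serialized.
    calibration_note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.instrument_group is None and self.timestamp is not None:
            self.instrument_group = GROUP_BY_YEAR.get(self.timestamp.year)
        if self.instrument_group is not None and self.instrument_group not in INSTRUMENT_GROUPS:
            raise ValueError(f"unknown instrument group {self.instrument_group!r}")

    def validate(self, row: Optional[int] = None) -> None:
        """Range-check fields; out-of-range values warn rather than fail.

        Field instruments can legitimately be used off-plateau (access routes)
        and a meter glitch should surface loudly without dropping the row.
        """
        where = "" if row is None else f" (row {row})"
        if self.longitude is not None and self.latitude is not None:
            if not (
                PLATEAU_WEST <= self.longitude <= PLATEAU_EAST
                and PLATEAU_SOUTH <= self.latitude <= PLATEAU_NORTH
            ):
                warnings.warn(
                    f"point ({self.longitude}, {self.latitude}) outside the "
                    f"plateau raster extent{where}",
                    stacklevel=2,
                )
        oc = self.oxygen_concentration
        if oc is not None and not (0.0 < oc <= 30.0):
            warnings.warn(
                f"oxygen concentration {oc} outside (0, 30] meter range{where}",
                stacklevel=2,
            )
        if self.elevation is not None and not (-500.0 <= self.elevation <= 9000.0):
            warnings.warn(f"elevation {self.elevation} outside [-500, 9000]{where}", stacklevel=2)
        if self.pressure is not None and not (300.0 < self.pressure < 1100.0):
            warnings.warn(f"pressure {self.pressure} outside (300, 1100){where}", stacklevel=2)

    @property
    def season(self) -> Optional[str]:
        """"summer" for months 6-8, "winter" for 11-2, else None."""
        if self.timestamp is None:
            return None
        m = self.timestamp.month
        if m in (6, 7, 8):
            return "summer"
        if m in (11, 12, 1, 2):
            return "winter"
        return None


@dataclass
class MeasurementTable:
    """An ordered collection of measurement records with a provenance tag."""

    records: list[MeasurementRecord] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        tids = [r.tid for r in self.records if r.tid is not None]
        if len(tids) != len(set(tids)):
            raise ValueError("duplicate TID values in measurement table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MeasurementRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MeasurementRecord:
        return self.records[i]

    def replace_records(self, records: Iterable[MeasurementRecord]) -> "MeasurementTable":
        return MeasurementTable(records=list(records), source=self.source)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view with the published column headers."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "TID": r.tid,
                    "FID": r.fid,
                    "Time": None if r.timestamp is None else r.timestamp.strftime("%Y/%m/%d %H:%M"),
                    "Longitude (°)": r.longitude,
                    "Latitude (°)": r.latitude,
                    "Elevation (m)": r.elevation,
                    "Temperature (°C)": r.temperature,
                    "Relative humidity (%)": r.relative_humidity,
                    "Atmospheric pressure (hpa)": r.pressure,
                    "Oxygen concentration (%)": r.oxygen_concentration,
                    "FVC (%)": r.fvc,
                    "Geomorphologic type": r.geomorph_type,
                    "Vegetation type": r.vegetation_type,
                    "Instrument group": r.instrument_group,
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS + ["Instrument group"])


def _norm_header(name: str) -> str:
    """Lower-case a header and strip any unit parenthetical."""
    name = str(name)
    if "(" in name:
        name = name[: name.index("(")]
    return name.strip().lower()


def _is_absent(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    s = str(cell).strip()
    return s == "" or s == "/" or s.lower() == "nan"


def _parse_float(cell, row: int, column: str) -> float:
    s = str(cell).strip()
    # Locale-strict: decimal point only; commas are never thousands separators.
    if "," in s:
        raise RowParseError(row, f"invalid numeric value {s!r} in column {column!r}")
    try:
        return float(s)
    except ValueError:
        raise RowParseError(row, f"invalid numeric value {s!r} in column {column!r}") from None


def _parse_time(cell, row: int) -> datetime:
    if isinstance(cell, datetime):
        return cell
    if isinstance(cell, pd.Timestamp):
        return cell.to_pydatetime()
    s = str(cell).strip()
    for fmt in _TIME_FORMATS:
        try:
            return datetime.strptime(s, fmt)
        except ValueError:
            pass
    try:
        return datetime.fromisoformat(s)
    except ValueError:
        raise RowParseError(row, f"unparseable timestamp {s!r}") from None


def read_measurements(path, dialect: Optional[str] = None) -> MeasurementTable:
    """Read a measurement table from CSV or a spreadsheet workbook.

    Parameters
    ----------
    path
        Input file.  ``dialect`` ("csv" or "xlsx") overrides the extension.

    Header match is case-insensitive and ignores unit parentheticals; optional
    columns may be missing entirely.  "/" and empty cells map to absent values.

    Raises
    ------
    SchemaError
        If a mandatory column (longitude, latitude, elevation, oxygen
        concentration) is missing.
    RowParseError
        If a numeric or timestamp cell cannot be parsed (carries row index).
    """
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if dialect == "xlsx":
        df = pd.read_excel(path, dtype=object)
    elif dialect == "csv":
        df = pd.read_csv(path, dtype=object, keep_default_na=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    col_for_field: dict[str, str] = {}
    for col in df.columns:
        fld = _FIELD_BY_KEY.get(_norm_header(col))
        if fld is not None and fld not in col_for_field:
            col_for_field[fld] = col
    for fld in _MANDATORY:
        if fld not in col_for_field:
            raise SchemaError(f"missing mandatory column {fld!r} in {path.name}")

    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        kwargs = {}
        for fld, col in col_for_field.items():
            cell = row[col]
            if _is_absent(cell):
                if fld in _MANDATORY:
                    raise RowParseError(i, f"missing value in mandatory column {fld!r}")
                continue
            if fld in _NUMERIC:
                kwargs[fld] = _parse_float(cell, i, col)
            elif fld == "timestamp":
                kwargs[fld] = _parse_time(cell, i)
            else:
                kwargs[fld] = str(cell).strip()
        rec = MeasurementRecord(**kwargs)
        rec.validate(row=i)
        records.append(rec)
    return MeasurementTable(records=records, source=str(path))


def write_measurements(table: MeasurementTable, path, dialect: Optional[str] = None):
    """Write a table to CSV or xlsx; round-trips through :func:`read_measurements`.

    Absent optional values are written as "/" (the published sentinel); numeric
    fields are written at full float precision.
    """
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    df = table.to_dataframe()
    if dialect == "csv":
        out = df.map(lambda v: "/" if v is None else (repr(v) if isinstance(v, float) else v))
        out.to_csv(path, index=False, encoding="utf-8")
    elif dialect == "xlsx":
        out = df.map(lambda v: "/" if v is None else v)
        out.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def load_reference_points() -> MeasurementTable:
    """The bundled 13-point Qinghai Lake route sample (August 2018)."""
    with importlib.resources.as_file(
        importlib.resources.files("oxymap.data") / "qinghai_lake_2018.csv"
    ) as p:
        table = read_measurements(p, dialect="csv")
    return replace(table, source="qinghai_lake_2018")
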