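"""Reading, filtering and grid-assigning dated point-locality occurrence records.

Records are presence-only sightings: a species identity, a coordinate, and a
dating interval.  A record enters the analysis only if it is dated to within
±10 years (interval width ≤ 20 yr) or carries a confident pre/post flag
relative to the cutoff year (default 1980).  Records whose interval straddles
the cutoff without such a flag cannot be placed on either side and are
excluded from all downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .grid import GridSpec, cell_of, project

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceRecord",
    "DatedPeriod",
    "ColumnMap",
    "read_occurrences",
    "assign_period",
    "grid_records",
    "write_gridded",
]

PRE, POST, NONE, EXCLUDED = "pre", "post", "none", "excluded"

#: maximum dating-interval width (years) for a record without a confident flag
MAX_INTERVAL_YEARS = 20


@dataclass(frozen=True)
class OccurrenceRecord:
    """One dated sighting of a species at a point locality."""

    species_id: str
    lon: float
    lat: float
    year_min: Optional[int] = None
    year_max: Optional[int] = None
    confident_period: str = NONE  # 'pre' | 'post' | 'none'

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if not (-180 <= self.lon <= 180 and -90 <= self.lat <= 90):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")
        if (
            self.year_min is not None
            and self.year_max is not None
            and self.year_min > self.year_max
        ):
            raise ValueError("year_min > year_max")
        if self.confident_period not in (PRE, POST, NONE):
            raise ValueError(f"invalid confident_period {self.confident_period!r}")


@dataclass(frozen=True)
class DatedPeriod:
    """Placement of one record relative to the cutoff year."""

    period: str  # 'pre' | 'post' | 'excluded'
    best_year: Optional[int] = None


@dataclass(frozen=True)
class ColumnMap:
    """Column-name mapping for delimited input; defaults follow Darwin Core."""

    species: str = "scientificName"
    lon: str = "decimalLongitude"
    lat: str = "decimalLatitude"
    year_min: str = "earliestDate"
    year_max: str = "latestDate"
    confident_period: str = "confidentPeriod"  # optional column


class SchemaError(ValueError):
    """Mandatory input columns are missing."""


def _parse_year(value) -> Optional[int]:
    """Extract a calendar year; dates finer than a year are truncated."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("na", "nan", "none"):
        return None
    # ISO-ish dates: leading 4 digits are the year
    head = s.split("-")[0].split("/")[0]
    return int(float(head))


def read_occurrences(source, columns: ColumnMap = ColumnMap(), sep: str = ",") -> list[OccurrenceRecord]:
    """Read occurrence records from a delimited text file or buffer.

    Malformed rows (unparseable coordinates or years, out-of-range values)
    are skipped and logged with their row number; missing mandatory columns
    raise :class:`SchemaError`.
    """
    df = pd.read_csv(source, sep=sep, dtype=str)
    mandatory = [columns.species, columns.lon, columns.lat]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    records: list[OccurrenceRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row_d = dict(zip(df.columns, row))
        try:
            conf = NONE
            if columns.confident_period in row_d:
                raw = row_d[columns.confident_period]
                if raw is not None and str(raw).strip().lower() in (PRE, POST):
                    conf = str(raw).strip().lower()
            rec = OccurrenceRecord(
                species_id=str(row_d[columns.species]).strip(),
                lon=float(row_d[columns.lon]),
                lat=float(row_d[columns.lat]),
                year_min=_parse_year(row_d.get(columns.year_min)),
                year_max=_parse_year(row_d.get(columns.year_max)),
                confident_period=conf,
            )
        except (ValueError, TypeError) as exc:
            logger.warning("row %d skipped: %s", i, exc)
            continue
        records.append(rec)
    return records


def assign_period(rec: OccurrenceRecord, cutoff_year: int = 1980) -> DatedPeriod:
    """Place a record before or after the cutoff, or exclude it.

    Inclusion rule: the dating interval must be no wider than
    ``MAX_INTERVAL_YEARS`` (±10 yr), or the record must carry a confident
    pre/post flag.  An included record is *pre* if its interval ends before
    the cutoff, *post* if it starts at or after it; an interval straddling
    the cutoff falls back on the confident flag or is excluded.

    ``best_year`` is the interval midpoint (floored) where years are known.
    """
    y0, y1 = rec.year_min, rec.year_max
    if y0 is not None and y1 is not None:
        best = (y0 + y1) // 2
        well_dated = (y1 - y0) <= MAX_INTERVAL_YEARS
        included = well_dated or rec.confident_period != NONE
        if y1 < cutoff_year:
            period = PRE if included else EXCLUDED
        elif y0 >= cutoff_year:
            period = POST if included else EXCLUDED
        else:  # straddles the cutoff: only a confident flag can place it
            period = rec.confident_period if rec.confident_period != NONE else EXCLUDED
            best = None if period == EXCLUDED else best
        return DatedPeriod(period, best if period != EXCLUDED else None)
    if rec.confident_period != NONE:
        # confidently placed but not year-dated; usable for period-level
        # analyses, not for the per-year sighting model
        return DatedPeriod(rec.confident_period, None)
    return DatedPeriod(EXCLUDED, None)


def grid_records(
    records: Iterable[OccurrenceRecord],
    spec: GridSpec = GridSpec(),
    cutoff_year: int = 1980,
) -> pd.DataFrame:
    """Period-assign records, drop excluded ones, and map the rest to cells.

    Returns one row per retained record with columns
    ``species_id, ix, iy, period, best_year`` (record counts are conserved:
    retained records in == rows out).
    """
    rows = []
    for rec in records:
        dp = assign_period(rec, cutoff_year)
        if dp.period == EXCLUDED:
            continue
        x, y = project(rec.lon, rec.lat, spec)
        cell = cell_of(x, y, spec)
        rows.append((rec.species_id, cell.ix, cell.iy, dp.period, dp.best_year))
    df = pd.DataFrame(rows, columns=["species_id", "ix", "iy", "period", "best_year"])
    df["best_year"] = df["best_year"].astype("Int64")
    return df


def write_gridded(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
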