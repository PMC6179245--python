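"""Camera-trap record ingest and detection-history construction.

A camera-trap survey is a set of fixed stations, each active over one or
more date windows, photographing whatever passes.  This module turns the
raw time-stamped photographic records into the sites x occasions binary
detection history that a single-season occupancy model consumes:

* records are collapsed into *independent events* (photographic bursts of
  the same species at the same station separated by no more than a fixed
  gap count as one event);
* the survey timeline is cut into fixed-length occasions (weekly bins by
  default) on a single global calendar shared by all stations;
* per-station sampling effort (active trap-days per occasion) determines
  which cells of the history are observed and which are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionRecord",
    "StationInfo",
    "OccasionGrid",
    "DetectionHistory",
    "read_records",
    "read_stations",
    "filter_independent",
    "compute_effort",
    "build_detection_history",
    "tabulate_by_zone",
]

ZONES = ("national_park", "wma", "village_land")
TRAIL_TYPES = ("AT", "NT", "RD")


@dataclass(frozen=True, order=True)
class DetectionRecord:
    """One time-stamped photographic capture of a species at a station."""

    station_id: str
    species: str
    timestamp: pd.Timestamp


@dataclass
class StationInfo:
    """A camera-trap station: location, grouping labels and active windows.

    ``active_windows`` are half-open date intervals ``[start, end)``; a
    station is active on day ``d`` iff ``start <= d < end`` for some
    window.  Windows must be non-overlapping with ``start < end``.
    """

    station_id: str
    x: float
    y: float
    area: str
    zone: str
    trail_type: str
    active_windows: list[tuple[date, date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"station {self.station_id}: unknown zone {self.zone!r}")
        if self.trail_type not in TRAIL_TYPES:
            raise ValueError(
                f"station {self.station_id}: trail_type must be one of {TRAIL_TYPES}, "
                f"got {self.trail_type!r}"
            )
        wins = sorted(self.active_windows)
        for start, end in wins:
            if not start < end:
                raise ValueError(
                    f"station {self.station_id}: empty or inverted window ({start}, {end})"
                )
        for (_, e1), (s2, _) in zip(wins, wins[1:]):
            if s2 < e1:
                raise ValueError(f"station {self.station_id}: overlapping active windows")
        self.active_windows = wins

    @property
    def total_active_days(self) -> int:
        return sum((end - start).days for start, end in self.active_windows)


@dataclass(frozen=True)
class OccasionGrid:
    """Global occasion calendar: ``n_occasions`` bins of ``occasion_days`` days."""

    start: date
    n_occasions: int = 32
    occasion_days: int = 7

    def __post_init__(self) -> None:
        if self.n_occasions < 1 or self.occasion_days < 1:
            raise ValueError("n_occasions and occasion_days must be positive")

    @property
    def end(self) -> date:
        return self.start + timedelta(days=self.n_occasions * self.occasion_days)

    def occasion_bounds(self, j: int) -> tuple[date, date]:
        """Half-open date bounds ``[start, end)`` of occasion ``j`` (0-based)."""
        s = self.start + timedelta(days=j * self.occasion_days)
        return s, s + timedelta(days=self.occasion_days)

    def occasion_of(self, ts: pd.Timestamp) -> int:
        """0-based occasion index containing ``ts``; -1 if outside the grid."""
        offset = (ts.date() - self.start).days
        if offset < 0 or offset >= self.n_occasions * self.occasion_days:
            return -1
        return offset // self.occasion_days


@dataclass
class DetectionHistory:
    """Sites x occasions matrix of {0, 1, missing} with per-cell effort.

    ``y`` is float with NaN for missing cells; ``effort_days`` counts the
    active trap-days in each (site, occasion) cell.  Invariant: ``y`` is
    NaN exactly where ``effort_days == 0``.
    """

    sites: list[str]
    y: np.ndarray
    effort_days: np.ndarray
    grid: OccasionGrid

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.effort_days = np.asarray(self.effort_days, dtype=int)
        if self.y.shape != self.effort_days.shape:
            raise ValueError("y and effort_days must have the same shape")
        if self.y.shape != (len(self.sites), self.grid.n_occasions):
            raise ValueError("history shape inconsistent with sites/grid")
        miss = np.isnan(self.y)
        if np.any(miss != (self.effort_days == 0)):
            raise ValueError("y must be missing exactly where effort_days == 0")
        observed = self.y[~miss]
        if not np.all(np.isin(observed, (0.0, 1.0))):
            raise ValueError("observed y entries must be 0 or 1")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_occasions(self) -> int:
        return self.grid.n_occasions

    def naive_use(self) -> np.ndarray:
        """1 for sites with at least one detection, else 0."""
        return (np.nansum(self.y, axis=1) > 0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"occ{j + 1}" for j in range(self.n_occasions)]
        return pd.DataFrame(self.y, index=pd.Index(self.sites, name="station_id"), columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path, effort_days: np.ndarray, grid: OccasionGrid) -> "DetectionHistory":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), effort_days, grid)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowParseError(ValueError):
    """One or more data rows failed to parse."""

    def __init__(self, message: str, bad_rows: list[int]):
        super().__init__(message)
        self.bad_rows = bad_rows


_DEFAULT_SCHEMA = {"station_id": "station_id", "species": "species", "timestamp": "timestamp"}


def read_records(path, schema: Mapping[str, str] | None = None, *,
                 permissive: bool = False) -> list[DetectionRecord]:
    """Read time-stamped capture records from a delimited text file.

    ``schema`` maps the logical fields (station_id, species, timestamp) to
    column names in the file.  Rows with unparseable timestamps abort the
    run (listing the offending row numbers) unless ``permissive`` is set,
    in which case they are dropped.  Exact duplicates are dropped; records
    come back sorted by (station_id, species, timestamp).
    """
    schema = dict(_DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}; found {list(df.columns)}")
    ts = pd.to_datetime(df[schema["timestamp"]], errors="coerce", format="ISO8601")
    bad = ts.isna() & df[schema["timestamp"]].notna()
    bad |= df[schema["timestamp"]].isna()
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]  # 1-based incl. header
        if not permissive:
            raise RowParseError(
                f"{len(rows)} row(s) with unparseable timestamp (file line numbers: {rows})",
                rows,
            )
        df, ts = df[~bad], ts[~bad]
    out = pd.DataFrame(
        {
            "station_id": df[schema["station_id"]].astype(str),
            "species": df[schema["species"]].astype(str),
            "timestamp": ts,
        }
    ).drop_duplicates()
    out = out.sort_values(["station_id", "species", "timestamp"])
    return [
        DetectionRecord(r.station_id, r.species, pd.Timestamp(r.timestamp))
        for r in out.itertuples(index=False)
    ]


_STATION_COLS = ["station_id", "x", "y", "area", "zone", "trail_type", "start", "end"]


def read_stations(path) -> list[StationInfo]:
    """Read a station table; one row per active window, grouped by station.

    Columns: station_id, x, y, area, zone, trail_type, start, end (ISO
    dates, window half-open).  Stations with several windows repeat their
    metadata on each row.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _STATION_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    stations = []
    for sid, grp in df.groupby("station_id", sort=True):
        first = grp.iloc[0]
        windows = [
            (pd.Timestamp(s).date(), pd.Timestamp(e).date())
            for s, e in zip(grp["start"], grp["end"])
            if pd.notna(s) and pd.notna(e)
        ]
        stations.append(
            StationInfo(
                station_id=str(sid),
                x=float(first["x"]),
                y=float(first["y"]),
                area=str(first["area"]),
                zone=str(first["zone"]),
                trail_type=str(first["trail_type"]),
                active_windows=windows,
            )
        )
    return stations


def filter_independent(records: Sequence[DetectionRecord],
                       window_minutes: float = 5.0) -> list[DetectionRecord]:
    """Collapse bursts into independent events (chained gap rule).

    Within each (station, species) group, a record is retained iff its gap
    to the previously *retained* record is strictly greater than
    ``window_minutes``; the first record of each group is always retained.
    The rule is idempotent: running the filter twice changes nothing.
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be non-negative")
    window = pd.Timedelta(minutes=window_minutes)
    out: list[DetectionRecord] = []
    last_kept: dict[tuple[str, str], pd.Timestamp] = {}
    for rec in sorted(records):
        key = (rec.station_id, rec.species)
        prev = last_kept.get(key)
        if prev is not None and not rec.timestamp - prev > window:
            continue
        last_kept[key] = rec.timestamp
        out.append(rec)
    return out


def compute_effort(stations: Sequence[StationInfo], grid: OccasionGrid,
                   *, warn: bool = True) -> np.ndarray:
    """Active trap-days per (station, occasion).

    Entry (i, j) is the number of days of occasion j that intersect station
    i's active windows; a station's row sums to its total window length.
    Raises if any window extends beyond the grid.
    """
    import warnings

    effort = np.zeros((len(stations), grid.n_occasions), dtype=int)
    for i, st in enumerate(stations):
        if not st.active_windows and warn:
            warnings.warn(f"station {st.station_id} has no active windows; zero effort row")
        for start, end in st.active_windows:
            if start < grid.start or end > grid.end:
                raise ValueError(
                    f"station {st.station_id}: window ({start}, {end}) outside the "
                    f"occasion grid [{grid.start}, {grid.end})"
                )
            for j in range(grid.n_occasions):
                os, oe = grid.occasion_bounds(j)
                overlap = (min(end, oe) - max(start, os)).days
                if overlap > 0:
                    effort[i, j] += overlap
    return effort


def build_detection_history(records: Sequence[DetectionRecord],
                            stations: Sequence[StationInfo],
                            grid: OccasionGrid,
                            species: str | None = None) -> DetectionHistory:
    """Bin independence-filtered records of the focal species into a history.

    ``y[i, j]`` is 1 if at least one record fell at station i in occasion
    j, 0 if the station was active but recorded nothing, and missing where
    effort is zero.  A record at an unknown station, outside the grid, or
    inside a zero-effort cell is an inconsistency and raises.
    """
    if species is not None:
        records = [r for r in records if r.species == species]
    site_index = {st.station_id: i for i, st in enumerate(stations)}
    orphans = sorted({r.station_id for r in records} - set(site_index))
    if orphans:
        raise ValueError(f"records at station(s) absent from the station table: {orphans}")
    effort = compute_effort(stations, grid)
    y = np.where(effort > 0, 0.0, np.nan)
    for rec in records:
        i = site_index[rec.station_id]
        j = grid.occasion_of(rec.timestamp)
        if j < 0:
            raise ValueError(
                f"record at {rec.station_id} {rec.timestamp} falls outside the occasion grid"
            )
        if effort[i, j] == 0:
            raise ValueError(
                f"record at {rec.station_id} {rec.timestamp} falls in a zero-effort "
                f"occasion {j + 1}; records and effort windows are inconsistent"
            )
        y[i, j] = 1.0
    return DetectionHistory(list(site_index), y, effort, grid)


def tabulate_by_zone(history: DetectionHistory,
                     records: Sequence[DetectionRecord],
                     stations: Sequence[StationInfo]) -> pd.DataFrame:
    """Per-zone survey summary: stations, stations with detections,
    independent events and total effort days."""
    by_id = {st.station_id: st for st in stations}
    naive = dict(zip(history.sites, history.naive_use()))
    effort_by_site = dict(zip(history.sites, history.effort_days.sum(axis=1)))
    rows = {}
    for zone in ZONES:
        sts = [s for s in stations if s.zone == zone]
        ids = {s.station_id for s in sts}
        rows[zone] = {
            "n_stations": len(sts),
            "n_stations_detected": int(sum(naive.get(s.station_id, 0) for s in sts)),
            "n_events": sum(1 for r in records if by_id[r.station_id].zone == zone),
            "effort_days": int(sum(effort_by_site.get(i, 0) for i in ids)),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("zone")
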