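"""Ingestion, validation and quality filtering of tracking and weather data.

Canonical units throughout the package are kPa (pressure) and km/h (wind and
flight speed); converters live only at this I/O boundary.  All timestamps
are UTC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import haversine_km

__all__ = [
    "SchemaError",
    "IngestReport",
    "StationSeries",
    "StormEvent",
    "read_tracks",
    "read_station",
    "write_station",
    "speed_filter",
    "split_bursts",
    "PRESSURE_TO_KPA",
    "WIND_TO_KMH",
]

PRESSURE_TO_KPA = {"kPa": 1.0, "hPa": 0.1, "inHg": 3.3863886666667}
WIND_TO_KMH = {"km/h": 1.0, "m/s": 3.6, "knots": 1.852}

DEFAULT_TRACK_SCHEMA = {"id": "id", "timestamp": "timestamp", "lon": "lon", "lat": "lat"}


class SchemaError(ValueError):
    """Input file does not carry the declared columns or units."""


@dataclass
class IngestReport:
    """Row-level QC outcome of one ingestion pass."""

    n_rows: int = 0
    n_kept: int = 0
    bad_timestamp: list[int] = field(default_factory=list)  # 1-based line numbers
    out_of_bounds: list[int] = field(default_factory=list)
    duplicates: list[int] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.bad_timestamp) + len(self.out_of_bounds) + len(self.duplicates)


@dataclass
class StationSeries:
    """Hourly weather-station series in canonical units (kPa, km/h).

    ``data`` has columns ``t`` (UTC hourly timestamps on a full grid),
    ``bp_kpa`` and ``wv_kmh``; missing hours are explicit NaN rows.
    """

    station_id: str
    data: pd.DataFrame
    month: str  # "YYYY-MM"

    def in_window(self, start, end) -> pd.DataFrame:
        m = (self.data["t"] >= pd.Timestamp(start)) & (self.data["t"] <= pd.Timestamp(end))
        return self.data.loc[m].reset_index(drop=True)


@dataclass
class StormEvent:
    name: str
    landfall_t: pd.Timestamp
    month: str
    station_id: str

    def __post_init__(self):
        self.landfall_t = pd.Timestamp(self.landfall_t)
        if self.landfall_t.strftime("%Y-%m") != self.month:
            raise ValueError(f"landfall {self.landfall_t} outside month {self.month}")


def read_tracks(source, schema: dict | None = None) -> tuple[dict[str, pd.DataFrame], IngestReport]:
    """Read a tracking CSV into per-individual, time-sorted fix tables.

    Malformed rows (unparseable timestamp, coordinates out of bounds,
    duplicated (id, t)) are counted in the report with their line numbers
    and skipped, never imputed.

    Returns ``(fixes_by_id, report)`` where each value is a DataFrame with
    columns ``individual_id``, ``t``, ``lon``, ``lat`` sorted by ``t``.
    """
    colmap = dict(DEFAULT_TRACK_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(source, dtype={colmap["id"]: str})
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise SchemaError(f"tracking file lacks columns: {missing}")

    report = IngestReport(n_rows=len(raw))
    # line numbers are 1-based and count the header line
    lines = raw.index.to_numpy() + 2

    t = pd.to_datetime(raw[colmap["timestamp"]], utc=True, errors="coerce")
    bad_t = t.isna()
    report.bad_timestamp = [int(x) for x in lines[bad_t]]

    lon = pd.to_numeric(raw[colmap["lon"]], errors="coerce")
    lat = pd.to_numeric(raw[colmap["lat"]], errors="coerce")
    oob = (~bad_t) & (lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90))
    report.out_of_bounds = [int(x) for x in lines[oob]]

    ok = ~(bad_t | oob)
    df = pd.DataFrame({
        "individual_id": raw[colmap["id"]],
        "t": t.dt.tz_localize(None),
        "lon": lon,
        "lat": lat,
        "_line": lines,
    }).loc[ok]
    df = df.sort_values(["individual_id", "t", "_line"], kind="stable")
    dup = df.duplicated(subset=["individual_id", "t"], keep="first")
    report.duplicates = [int(x) for x in df.loc[dup, "_line"]]
    if dup.any():
        warnings.warn(f"rejected {int(dup.sum())} duplicate (id, t) rows")
    df = df.loc[~dup].drop(columns="_line").reset_index(drop=True)
    report.n_kept = len(df)

    out = {str(ind): g.reset_index(drop=True) for ind, g in df.groupby("individual_id", sort=True)}
    return out, report


def read_station(source, pressure_unit: str = "hPa", wind_unit: str = "km/h",
                 station_id: str = "", schema: dict | None = None,
                 month: str | None = None) -> StationSeries:
    """Read an hourly station export and normalize to kPa / km/h.

    ``schema`` may remap the expected columns ``timestamp``, ``pressure``,
    ``wind``.  Records are re-indexed onto the full hourly grid of the
    covered month so that gaps are explicit NaNs.
    """
    if pressure_unit not in PRESSURE_TO_KPA:
        raise SchemaError(f"unknown pressure unit {pressure_unit!r}; "
                          f"expected one of {sorted(PRESSURE_TO_KPA)}")
    if wind_unit not in WIND_TO_KMH:
        raise SchemaError(f"unknown wind unit {wind_unit!r}; "
                          f"expected one of {sorted(WIND_TO_KMH)}")
    colmap = {"timestamp": "timestamp", "pressure": "pressure", "wind": "wind"}
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(source)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing and not schema and {"t", "bp_kpa", "wv_kmh"} <= set(raw.columns):
        # the writer's canonical schema: column names declare the units
        colmap = {"timestamp": "t", "pressure": "bp_kpa", "wind": "wv_kmh"}
        pressure_unit, wind_unit = "kPa", "km/h"
        missing = []
    if missing:
        raise SchemaError(f"station file lacks columns: {missing}")

    t = pd.to_datetime(raw[colmap["timestamp"]], utc=True).dt.tz_localize(None)
    bp = pd.to_numeric(raw[colmap["pressure"]], errors="coerce") * PRESSURE_TO_KPA[pressure_unit]
    wv = pd.to_numeric(raw[colmap["wind"]], errors="coerce") * WIND_TO_KMH[wind_unit]
    df = pd.DataFrame({"t": t.dt.floor("h"), "bp_kpa": bp, "wv_kmh": wv})
    df = df.groupby("t", as_index=False).mean()

    if month is None:
        month = pd.Timestamp(df["t"].iloc[0]).strftime("%Y-%m")
    start = pd.Timestamp(month + "-01")
    grid = pd.date_range(start, start + pd.offsets.MonthBegin(1) - pd.Timedelta(hours=1),
                         freq="h")
    df = df.set_index("t").reindex(grid).rename_axis("t").reset_index()

    bad_bp = df["bp_kpa"].notna() & ((df["bp_kpa"] < 90) | (df["bp_kpa"] > 110))
    bad_wv = df["wv_kmh"].notna() & (df["wv_kmh"] < 0)
    if bad_bp.any() or bad_wv.any():
        warnings.warn(f"masked {int(bad_bp.sum())} implausible pressure and "
                      f"{int(bad_wv.sum())} negative wind readings")
        df.loc[bad_bp, "bp_kpa"] = np.nan
        df.loc[bad_wv, "wv_kmh"] = np.nan
    return StationSeries(station_id=station_id, data=df, month=month)


def write_station(series: StationSeries, path) -> None:
    """Write the canonical kPa / km/h hourly schema."""
    series.data.to_csv(path, index=False)


def speed_filter(fixes: pd.DataFrame, vmax: float = 65.0
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove fixes whose arrival speed from the previous kept fix is >= vmax.

    Sequential greedy pass: the first fix is always kept; each candidate is
    tested against the last *kept* fix, so a removed teleport does not
    poison its successor.  Idempotent: the kept output contains no pair at
    or above ``vmax``.

    Returns ``(kept, removed)`` where ``removed`` carries the offending
    computed speed in column ``speed_kmh``.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    if len(fixes) < 2:
        return fixes.reset_index(drop=True), fixes.iloc[0:0].assign(speed_kmh=np.nan)
    t = pd.to_datetime(fixes["t"]).to_numpy()
    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    keep = [0]
    removed_idx, removed_speed = [], []
    for i in range(1, len(fixes)):
        j = keep[-1]
        dt_h = (t[i] - t[j]).astype("timedelta64[s]").astype(float) / 3600.0
        if dt_h <= 0:
            removed_idx.append(i)
            removed_speed.append(np.inf)
            continue
        v = float(haversine_km(lon[j], lat[j], lon[i], lat[i])) / dt_h
        if v >= vmax:
            removed_idx.append(i)
            removed_speed.append(v)
        else:
            keep.append(i)
    kept = fixes.iloc[keep].reset_index(drop=True)
    removed = fixes.iloc[removed_idx].assign(speed_kmh=removed_speed).reset_index(drop=True)
    return kept, removed


def split_bursts(fixes: pd.DataFrame, max_gap_h: float = 6.0) -> pd.DataFrame:
    """Partition a sorted fix sequence into bursts at gaps > ``max_gap_h``.

    The default of 6 h (4x the 90-min fix interval) guarantees the 36-h
    transmitter off-cycle always starts a new burst.  Returns a copy with
    an integer ``burst_id`` column; concatenated bursts reproduce the input
    order exactly.
    """
    out = fixes.reset_index(drop=True).copy()
    if len(out) == 0:
        out["burst_id"] = pd.Series(dtype=int)
        return out
    t = pd.to_datetime(out["t"]).to_numpy()
    gaps_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
    out["burst_id"] = np.concatenate([[0], np.cumsum(gaps_h > max_gap_h)]).astype(int)
    return out
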