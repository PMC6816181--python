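"""Meteorological statistics, pressure-anomaly runs, and the study window.

An anomalous hour is a barometric-pressure reading at least one monthly
standard deviation from the monthly mean (two-sided by default; cyclones
are pressure dips, so a low-side-only mode exists).  Maximal contiguous
anomalous hours form anomaly runs; the cyclone run is the one containing
the monthly pressure minimum (or an explicit landfall hint).  The study
window runs from the end of the last pre-cyclone anomaly run to the start
of the first post-cyclone run, so it contains the cyclone plus otherwise
baseline conditions only.  Wind never enters anomaly detection; it enters
the regression stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import StationSeries

__all__ = [
    "AnomalyRun",
    "StudyWindow",
    "monthly_stats",
    "detect_anomalies",
    "study_window",
    "match_weather",
    "window_report_row",
    "plot_weather_series",
]


@dataclass
class AnomalyRun:
    start_t: pd.Timestamp        # inclusive hourly bounds
    end_t: pd.Timestamp
    kind: str                    # 'pre' | 'cyclone' | 'post' | ''
    extreme_kpa: float           # most extreme pressure within the run

    @property
    def n_hours(self) -> int:
        return int((self.end_t - self.start_t) / pd.Timedelta(hours=1)) + 1


@dataclass
class StudyWindow:
    start_t: pd.Timestamp
    end_t: pd.Timestamp
    cyclone_run: AnomalyRun

    def contains(self, t) -> np.ndarray:
        t = pd.to_datetime(t)
        return (t >= self.start_t) & (t <= self.end_t)


def monthly_stats(series: StationSeries) -> dict:
    """Monthly summary in the meteorology-table shape (sample SDs, NaN hours
    skipped)."""
    bp = series.data["bp_kpa"].dropna()
    wv = series.data["wv_kmh"].dropna()
    if len(bp) < 2:
        raise ValueError("need at least 2 non-missing pressure records")
    return {
        "bp_mean_kpa": float(bp.mean()),
        "bp_sd_kpa": float(bp.std(ddof=1)),
        "bp_min_kpa": float(bp.min()),
        "wv_mean_kmh": float(wv.mean()) if len(wv) else np.nan,
        "wv_sd_kmh": float(wv.std(ddof=1)) if len(wv) > 1 else np.nan,
        "wv_max_kmh": float(wv.max()) if len(wv) else np.nan,
    }


def detect_anomalies(series: StationSeries, mean: float | None = None,
                     sd: float | None = None, side: str = "two") -> list[AnomalyRun]:
    """Maximal runs of hours whose pressure is >= 1 SD from the monthly mean.

    The criterion is inclusive: a reading exactly at mean - sd (or mean + sd
    under the two-sided rule) is anomalous.  Runs are broken by any
    non-anomalous or missing hour.
    """
    if mean is None or sd is None:
        stats = monthly_stats(series)
        mean = stats["bp_mean_kpa"] if mean is None else mean
        sd = stats["bp_sd_kpa"] if sd is None else sd
    if sd <= 0:
        raise ValueError("sd must be positive")
    df = series.data
    bp = df["bp_kpa"].to_numpy(dtype=float)
    if side == "two":
        flag = np.abs(bp - mean) >= sd
    elif side == "low":
        flag = (mean - bp) >= sd
    else:
        raise ValueError("side must be 'two' or 'low'")
    flag = np.where(np.isnan(bp), False, flag)

    runs: list[AnomalyRun] = []
    i = 0
    n = len(flag)
    while i < n:
        if flag[i]:
            j = i
            while j + 1 < n and flag[j + 1]:
                j += 1
            seg = bp[i:j + 1]
            ext = float(seg[np.nanargmax(np.abs(seg - mean))])
            runs.append(AnomalyRun(start_t=pd.Timestamp(df["t"].iloc[i]),
                                   end_t=pd.Timestamp(df["t"].iloc[j]),
                                   kind="", extreme_kpa=ext))
            i = j + 1
        else:
            i += 1
    return runs


def study_window(runs: list[AnomalyRun], series: StationSeries,
                 cyclone_hint=None) -> StudyWindow:
    """Bracket the cyclone run with the nearest surrounding anomaly runs.

    The cyclone run is the run containing the monthly pressure minimum, or
    the run containing ``cyclone_hint`` when given.  The window starts at
    the end of the latest run strictly before the cyclone run (month start
    if none) and ends at the start of the earliest run strictly after it
    (month end if none); the cyclone run itself stays inside the window.
    """
    if not runs:
        raise ValueError("no anomaly runs: cannot build a study window")
    if cyclone_hint is not None:
        hint = pd.Timestamp(cyclone_hint)
        cyc = [r for r in runs if r.start_t <= hint <= r.end_t]
        if not cyc:
            cand = ", ".join(f"[{r.start_t} .. {r.end_t}]" for r in runs)
            raise ValueError(f"cyclone hint {hint} falls in no anomaly run; "
                             f"candidates: {cand}")
        cyclone = cyc[0]
    else:
        bp = series.data["bp_kpa"]
        tmin = pd.Timestamp(series.data["t"].iloc[int(bp.idxmin())])
        cyc = [r for r in runs if r.start_t <= tmin <= r.end_t]
        if not cyc:
            raise ValueError("monthly pressure minimum lies in no anomaly run")
        cyclone = cyc[0]
    cyclone.kind = "cyclone"

    pre = [r for r in runs if r.end_t < cyclone.start_t]
    post = [r for r in runs if r.start_t > cyclone.end_t]
    for r in pre:
        r.kind = "pre"
    for r in post:
        r.kind = "post"
    start = max(r.end_t for r in pre) if pre else pd.Timestamp(series.data["t"].iloc[0])
    end = min(r.start_t for r in post) if post else pd.Timestamp(series.data["t"].iloc[-1])
    return StudyWindow(start_t=start, end_t=end, cyclone_run=cyclone)


def match_weather(fixes: pd.DataFrame, series: StationSeries,
                  max_gap_min: float = 90.0) -> pd.DataFrame:
    """Pair each fix with the nearest-in-time weather record.

    Ties at the exact midpoint resolve to the earlier record.  Pairs with
    |dt| > ``max_gap_min`` minutes (e.g. station outages) are dropped with
    a warning.  Returns the fixes with appended ``weather_t``, ``bp_kpa``,
    ``wv_kmh`` and ``dt_min`` columns.
    """
    wx = series.data.dropna(subset=["bp_kpa", "wv_kmh"], how="all").reset_index(drop=True)
    if wx.empty:
        raise ValueError("station series has no usable records")
    wt = pd.to_datetime(wx["t"]).to_numpy()
    ft = pd.to_datetime(fixes["t"]).to_numpy()
    pos = np.searchsorted(wt, ft)
    lo = np.clip(pos - 1, 0, len(wt) - 1)
    hi = np.clip(pos, 0, len(wt) - 1)
    d_lo = np.abs((ft - wt[lo]).astype("timedelta64[s]").astype(float))
    d_hi = np.abs((wt[hi] - ft).astype("timedelta64[s]").astype(float))
    take_lo = d_lo <= d_hi                      # earlier record wins ties
    idx = np.where(take_lo, lo, hi)
    dt_min = np.where(take_lo, d_lo, d_hi) / 60.0

    out = fixes.reset_index(drop=True).copy()
    out["weather_t"] = wt[idx]
    out["bp_kpa"] = wx["bp_kpa"].to_numpy()[idx]
    out["wv_kmh"] = wx["wv_kmh"].to_numpy()[idx]
    out["dt_min"] = dt_min
    far = out["dt_min"] > max_gap_min
    if far.any():
        warnings.warn(f"dropped {int(far.sum())} fixes more than "
                      f"{max_gap_min:.0f} min from any weather record")
    return out.loc[~far].reset_index(drop=True)


def window_report_row(event_name: str, series: StationSeries,
                      window: StudyWindow, n_locations: int) -> dict:
    """One meteorology-table row: cyclone, BP mean/SD/min, WV mean/SD/max,
    study period, location count."""
    s = monthly_stats(series)
    return {
        "cyclone": event_name,
        "bp_monthly_mean_kpa": round(s["bp_mean_kpa"], 2),
        "bp_monthly_sd_kpa": round(s["bp_sd_kpa"], 2),
        "bp_minimum_kpa": round(s["bp_min_kpa"], 2),
        "wv_monthly_mean_kmh": round(s["wv_mean_kmh"], 1),
        "wv_monthly_sd_kmh": round(s["wv_sd_kmh"], 1),
        "wv_maximum_kmh": round(s["wv_max_kmh"], 1),
        "study_period": f"{window.start_t:%d %b} - {window.end_t:%d %b %Y}",
        "locations_n": int(n_locations),
    }


def plot_weather_series(series_by_event: dict[str, StationSeries], path) -> None:
    """Hourly pressure and wind traces, one line per event."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=False)
    for name, s in series_by_event.items():
        hours = np.arange(len(s.data))
        ax1.plot(hours, s.data["bp_kpa"], lw=0.8, label=name)
        ax2.plot(hours, s.data["wv_kmh"], lw=0.8, label=name)
    ax1.set_ylabel("barometric pressure (kPa)")
    ax2.set_ylabel("wind velocity (km/h)")
    ax2.set_xlabel("hour of month")
    ax1.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
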