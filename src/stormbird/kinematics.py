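"""Per-step trajectory geometry: distances, speeds, bearings, turning angles.

All distances are great-circle on a sphere of radius 6371 km; ellipsoidal
geodesy is deliberately out of scope because net displacements in this
analysis stay well under a few hundred kilometres, where the spherical
approximation errs by < 0.5 %.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "initial_bearing_rad",
    "step_metrics",
    "net_displacement_km",
    "movement_summary",
    "write_feature_table",
]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays; symmetric and non-negative,
    zero iff the points coincide (to floating tolerance).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, in [0, 2*pi)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.mod(np.arctan2(y, x), 2.0 * np.pi)


def _wrap_turn(delta):
    """Wrap a bearing difference to an absolute turning angle in [0, pi]."""
    d = np.mod(np.asarray(delta, dtype=float), 2.0 * np.pi)
    return np.where(d > np.pi, 2.0 * np.pi - d, d)


def step_metrics(burst: pd.DataFrame, signed: bool = False) -> pd.DataFrame:
    """Per-step kinematics for one burst of fixes.

    Parameters
    ----------
    burst : DataFrame with columns ``t`` (UTC datetimes), ``lon``, ``lat``,
        sorted by time; a burst never spans a duty-cycle gap.
    signed : report the turning angle as the signed bearing change in
        (-pi, pi] instead of the default absolute angle in [0, pi].

    Returns
    -------
    DataFrame aligned to the *arrival* fix of each step (n fixes -> n-1
    rows) with columns ``t``, ``step_km``, ``dt_h``, ``speed_kmh``,
    ``bearing_rad``, ``turn_rad``.  The first step's turning angle is NaN
    (undefined).  Zero-length steps carry the last moving bearing forward;
    if no moving step precedes them, bearing and turn are NaN.
    """
    if len(burst) < 2:
        raise ValueError("step metrics need at least 2 fixes")
    t = pd.to_datetime(burst["t"]).to_numpy()
    lon = burst["lon"].to_numpy(dtype=float)
    lat = burst["lat"].to_numpy(dtype=float)
    dt_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
    if np.any(dt_h <= 0):
        raise ValueError("non-positive time step inside a burst")
    step = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    bearing = initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
    # stationary steps have no defined direction: carry the last moving
    # bearing forward so a subsequent move yields a meaningful turn
    moving = step > 1e-9
    carried = bearing.copy()
    last = np.nan
    for i in range(len(carried)):
        if moving[i]:
            last = bearing[i]
        else:
            carried[i] = last
    raw = np.diff(carried)
    if signed:
        d = np.mod(raw + np.pi, 2.0 * np.pi) - np.pi
        turn = np.concatenate([[np.nan], d])
    else:
        turn = np.concatenate([[np.nan], _wrap_turn(raw)])
    return pd.DataFrame(
        {
            "t": t[1:],
            "step_km": step,
            "dt_h": dt_h,
            "speed_kmh": step / dt_h,
            "bearing_rad": carried,
            "turn_rad": turn,
        }
    )


def net_displacement_km(fixes: pd.DataFrame) -> float:
    """Maximum great-circle distance of any fix from the first fix (km)."""
    if len(fixes) == 0:
        raise ValueError("need at least one fix")
    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    if len(lon) == 1:
        return 0.0
    return float(np.max(haversine_km(lon[0], lat[0], lon, lat)))


def movement_summary(steps_by_individual: dict[str, pd.DataFrame],
                     fixes_by_individual: dict[str, pd.DataFrame] | None = None
                     ) -> pd.DataFrame:
    """Cohort movement summary: mean +/- SD and range of step length, and of
    net displacement when fixes are supplied.

    Individuals with no steps are excluded with a warning.  SDs are sample
    standard deviations (ddof=1).
    """
    rows = []
    for ind, steps in steps_by_individual.items():
        if len(steps) == 0:
            warnings.warn(f"individual {ind!r} has no steps; excluded from summary")
            continue
        row = {"individual_id": ind,
               "n_steps": len(steps),
               "step_mean_km": float(steps["step_km"].mean()),
               "step_max_km": float(steps["step_km"].max())}
        if fixes_by_individual is not None and ind in fixes_by_individual:
            row["net_displacement_km"] = net_displacement_km(fixes_by_individual[ind])
        rows.append(row)
    per_ind = pd.DataFrame(rows)
    if per_ind.empty:
        raise ValueError("no individual contributed any step")

    all_steps = pd.concat([s["step_km"] for ind, s in steps_by_individual.items()
                           if len(s) > 0], ignore_index=True)
    out = [{"quantity": "step_length_km",
            "mean": float(all_steps.mean()),
            "sd": float(all_steps.std(ddof=1)) if len(all_steps) > 1 else 0.0,
            "min": float(all_steps.min()),
            "max": float(all_steps.max())}]
    if "net_displacement_km" in per_ind:
        nd = per_ind["net_displacement_km"]
        out.append({"quantity": "net_displacement_km",
                    "mean": float(nd.mean()),
                    "sd": float(nd.std(ddof=1)) if len(nd) > 1 else 0.0,
                    "min": float(nd.min()),
                    "max": float(nd.max())})
    return pd.DataFrame(out)


def write_feature_table(path, fixes: pd.DataFrame, steps: pd.DataFrame) -> None:
    """Write the per-fix (speed, turn) feature CSV consumed by the EMbC stage.

    Columns: individual_id, t, speed_kmh, turn_rad, burst_id.
    """
    merged = fixes.merge(steps[["t", "speed_kmh", "turn_rad"]], on="t", how="left")
    cols = [c for c in ("individual_id", "t", "speed_kmh", "turn_rad", "burst_id")
            if c in merged.columns]
    merged[cols].to_csv(path, index=False)
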