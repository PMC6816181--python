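"""Ground-truthed synthetic inputs: cyclone-month weather and GPS tracks.

The weather generator emits one calendar month of hourly station records:
an AR(1) pressure baseline with a Gaussian-shaped cyclone dip (plus
optional minor pre/post dips, emulating the ordinary weather systems that
bracket a real study window) and a wind series whose storm peak scales
with the dip.  Defaults echo the printed scales of the study system
(pressure ~101.3 +/- 0.4 kPa, storm minimum ~99.6 kPa, wind maximum in the
tens of km/h); they are scenario parameters, not fits to any real data.

The track generator is a duty-cycled, state-switching correlated random
walk: at each scheduled fix the bird is active with probability
inv-logit(b0 + b_bp * z_bp + b_wv * z_wv) on the month-standardized
weather; active substates (localized search, commuting, dispersive search)
follow a Markov switching matrix; step lengths come from state-specific
gamma speed distributions and headings evolve by wrapped-Cauchy turning
angles (centred at 0 for low-turn states, at pi for high-turn states).
A weak central-place tether keeps simulated ranges overlapping, as real
colony-based ranges do.  A configurable number of "absentee" individuals
live > 300 km away, providing the planted exclusions for the core-range
restriction stage.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import StationSeries
from .kinematics import EARTH_RADIUS_KM, haversine_km

__all__ = [
    "MetSimConfig",
    "MoveSimConfig",
    "simulate_weather",
    "simulate_tracks",
    "simulate_regression_data",
    "separable_features",
    "recovery_report",
    "irma_like_scenario",
]

STATE_INACTIVE, STATE_LOCAL, STATE_COMMUTE, STATE_DISPERSE = 0, 1, 2, 3


@dataclass
class MetSimConfig:
    """One synthetic cyclone month of hourly station weather."""

    month: str = "2017-09"
    bp_base_mean_kpa: float = 101.4
    bp_base_sd_kpa: float = 0.05         # stationary SD of the AR(1) baseline;
                                         # synoptic variability lives in the dips
    ar_coef: float = 0.9
    storm_day: float = 11.0              # day-of-month of the dip centre
    dip_depth_kpa: float = 1.8           # > 2x baseline SD by construction
    dip_half_width_h: float = 12.0
    minor_dips: tuple = ((4.0, 0.8, 5.0), (25.0, 0.8, 5.0))  # (day, depth, half-width)
    wv_base_mean_kmh: float = 9.0
    wv_base_sd_kmh: float = 3.0
    wv_storm_gain: float = 28.0          # km/h of wind per kPa of dip
    seed: int = 0

    def __post_init__(self):
        if self.dip_depth_kpa <= 2 * self.bp_base_sd_kpa:
            raise ValueError("dip depth must exceed 2x the baseline SD")
        if self.bp_base_sd_kpa <= 0 or self.wv_base_sd_kmh <= 0:
            raise ValueError("SDs must be positive")


@dataclass
class MoveSimConfig:
    """A cohort of duty-cycled, state-switching simulated trackers."""

    n_individuals: int = 40
    colony_lon: float = -80.0
    colony_lat: float = 32.5
    home_scatter_deg: float = 0.25       # per-bird home-centre jitter
    # per-state (mean speed km/h, gamma shape, turn centre rad, turn concentration)
    state_kinematics: dict = field(default_factory=lambda: {
        STATE_INACTIVE: (0.15, 4.0, 0.0, 0.7),
        STATE_LOCAL: (2.5, 4.0, np.pi, 0.4),
        STATE_COMMUTE: (12.0, 6.0, 0.0, 0.85),
        STATE_DISPERSE: (10.0, 4.0, np.pi, 0.35),
    })
    # Markov switching among active substates (rows/cols: local, commute, disperse)
    switching: tuple = ((0.6, 0.25, 0.15),
                       (0.3, 0.6, 0.1),
                       (0.35, 0.15, 0.5))
    beta: tuple = (0.6, 0.25, -0.20)     # (b0, b_bp, b_wv) on standardized weather
    fix_interval_h: float = 1.5
    on_hours: float = 8.0
    off_hours: float = 36.0
    max_fixes_per_day: int = 10
    gap_dt_cap_h: float = 4.0            # effective step duration across off-gaps
    tether_km: float = 40.0              # soft home-range radius
    shelter_z_bp: float = -1.0           # standardized-pressure level that
                                         # triggers sheltering at the refugium
    shelter_scatter_deg: float = 0.01    # per-bird refugium offset
    shelter_jitter_deg: float = 0.002    # arrival scatter at the refugium
    shelter_active_scatter_deg: float = 0.01   # localized flights around the
                                               # refugium while active in-storm
    n_absentees: int = 8
    absentee_offset_deg: float = 4.5     # >300 km poleward displacement
    seed: int = 0

    def __post_init__(self):
        sw = np.asarray(self.switching)
        if not np.allclose(sw.sum(axis=1), 1.0):
            raise ValueError("switching matrix rows must sum to 1")
        speeds = [self.state_kinematics[s][0] for s in
                  (STATE_INACTIVE, STATE_LOCAL, STATE_DISPERSE, STATE_COMMUTE)]
        if not (speeds[0] < speeds[1] < speeds[2] <= speeds[3]):
            raise ValueError("state mean speeds must satisfy "
                             "inactive < localized < dispersive <= commuting")


def _month_hours(month: str) -> pd.DatetimeIndex:
    start = pd.Timestamp(month + "-01")
    return pd.date_range(start, start + pd.offsets.MonthBegin(1) - pd.Timedelta(hours=1),
                         freq="h")


def simulate_weather(cfg: MetSimConfig) -> tuple[StationSeries, dict]:
    """Generate the monthly series and its truth record.

    The truth record stores the boolean anomalous-hour mask realized by the
    emitted series under the >=1-monthly-SD rule, the contiguous cyclone
    hours around the pressure minimum, and the dip centre time.
    """
    rng = np.random.default_rng(cfg.seed)
    t = _month_hours(cfg.month)
    n = len(t)
    hours = np.arange(n, dtype=float)

    innov_sd = cfg.bp_base_sd_kpa * np.sqrt(1.0 - cfg.ar_coef ** 2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, cfg.bp_base_sd_kpa)
    eps = rng.normal(0.0, innov_sd, size=n)
    for i in range(1, n):
        x[i] = cfg.ar_coef * x[i - 1] + eps[i]

    centre_h = (cfg.storm_day - 1.0) * 24.0
    dip = cfg.dip_depth_kpa * np.exp(-0.5 * ((hours - centre_h) / cfg.dip_half_width_h) ** 2)
    for day, depth, hw in cfg.minor_dips:
        dip += depth * np.exp(-0.5 * ((hours - (day - 1.0) * 24.0) / hw) ** 2)
    bp = cfg.bp_base_mean_kpa + x - dip

    wv_noise = np.abs(rng.normal(0.0, cfg.wv_base_sd_kmh, size=n))
    wv = np.maximum(cfg.wv_base_mean_kmh + wv_noise - cfg.wv_base_sd_kmh
                    + cfg.wv_storm_gain * dip, 0.0)

    series = StationSeries(station_id="SYNTH", month=cfg.month,
                           data=pd.DataFrame({"t": t, "bp_kpa": bp, "wv_kmh": wv}))

    # truth: the >= 1 SD rule applied directly to the emitted series
    anomalous = np.abs(bp - bp.mean()) >= bp.std(ddof=1)
    imin = int(np.argmin(bp))
    lo = imin
    while lo > 0 and anomalous[lo - 1]:
        lo -= 1
    hi = imin
    while hi < n - 1 and anomalous[hi + 1]:
        hi += 1
    truth = {
        "anomalous_hours": anomalous,
        "times": t,
        "cyclone_start": t[lo],
        "cyclone_end": t[hi],
        "storm_centre_t": t[int(round(centre_h))],
        "bp_threshold": float(bp.std(ddof=1)),
    }
    return series, truth


def _fix_schedule(t: pd.DatetimeIndex, cfg: MoveSimConfig,
                  phase_h: float) -> pd.DatetimeIndex:
    """Duty-cycled fix times within the month, 10-per-day cap enforced."""
    start = t[0] + pd.Timedelta(hours=phase_h)
    end = t[-1]
    cycle = cfg.on_hours + cfg.off_hours
    times = []
    t0 = start
    while t0 <= end:
        k = 0
        while k * cfg.fix_interval_h < cfg.on_hours:
            ft = t0 + pd.Timedelta(hours=k * cfg.fix_interval_h)
            if ft <= end:
                times.append(ft)
            k += 1
        t0 += pd.Timedelta(hours=cycle)
    idx = pd.DatetimeIndex(times)
    keep = []
    per_day: dict = {}
    for ft in idx:
        d = ft.normalize()
        per_day[d] = per_day.get(d, 0) + 1
        if per_day[d] <= cfg.max_fixes_per_day:
            keep.append(ft)
    return pd.DatetimeIndex(keep)


def _advance(lon, lat, bearing, dist_km):
    """Destination point on the sphere (degrees in/out, bearing rad)."""
    lat1 = np.radians(lat)
    lon1 = np.radians(lon)
    d = dist_km / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(d) + np.cos(lat1) * np.sin(d) * np.cos(bearing))
    lon2 = lon1 + np.arctan2(np.sin(bearing) * np.sin(d) * np.cos(lat1),
                             np.cos(d) - np.sin(lat1) * np.sin(lat2))
    return np.degrees(lon2), np.degrees(lat2)


def _wrapped_cauchy(rng, centre, rho, size=None):
    """Wrapped-Cauchy draw(s) in (-pi, pi] around ``centre``."""
    u = rng.uniform(0.0, 1.0, size=size)
    ang = 2.0 * np.arctan((1.0 - rho) / (1.0 + rho) * np.tan(np.pi * (u - 0.5)))
    return np.mod(centre + ang + np.pi, 2.0 * np.pi) - np.pi


def simulate_tracks(cfg: MoveSimConfig, weather: StationSeries
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cohort; returns ``(fixes, truth)`` DataFrames.

    ``fixes`` has columns individual_id, t, lon, lat (the tracking-CSV
    schema); ``truth`` additionally records the latent state4 / active
    flag per fix and the absentee flag per individual.
    """
    rng = np.random.default_rng(cfg.seed)
    wt = pd.DatetimeIndex(weather.data["t"])
    z_bp = _standardize(weather.data["bp_kpa"].to_numpy(dtype=float))
    z_wv = _standardize(weather.data["wv_kmh"].to_numpy(dtype=float))
    b0, b_bp, b_wv = cfg.beta
    sw = np.asarray(cfg.switching)

    fixes, truth = [], []
    for i in range(cfg.n_individuals):
        ind = f"PEL{i:02d}"
        absentee = i >= cfg.n_individuals - cfg.n_absentees
        home_lon = cfg.colony_lon + rng.normal(0.0, cfg.home_scatter_deg)
        home_lat = cfg.colony_lat + rng.normal(0.0, cfg.home_scatter_deg)
        if absentee:
            home_lat += cfg.absentee_offset_deg
            home_lon += rng.normal(1.0, 0.3)
        # storm refugium: a shared coastal site near the colony for the main
        # cohort, the bird's own distant range for absentees
        if absentee:
            shelter_lon, shelter_lat = home_lon, home_lat
        else:
            shelter_lon = cfg.colony_lon + rng.normal(0.0, cfg.shelter_scatter_deg)
            shelter_lat = cfg.colony_lat + rng.normal(0.0, cfg.shelter_scatter_deg)
        sched = _fix_schedule(wt, cfg, phase_h=float(rng.uniform(0.0, 24.0)))
        lon, lat = home_lon, home_lat
        heading = rng.uniform(0.0, 2.0 * np.pi)
        substate = STATE_LOCAL
        prev_t = None
        was_sheltering = False
        for ft in sched:
            hour_idx = int(np.clip(round((ft - wt[0]) / pd.Timedelta(hours=1)),
                                   0, len(wt) - 1))
            p_active = 1.0 / (1.0 + np.exp(-(b0 + b_bp * z_bp[hour_idx]
                                             + b_wv * z_wv[hour_idx])))
            active = rng.uniform() < p_active
            if active:
                substate = rng.choice(3, p=sw[substate - 1]) + 1
                state = substate
            else:
                state = STATE_INACTIVE
            sheltering = z_bp[hour_idx] <= cfg.shelter_z_bp
            if sheltering:
                # deep pressure anomaly: ride out the weather at the refugium;
                # inactive birds hold position, active ones make short
                # localized flights around it
                if not was_sheltering:
                    lon = shelter_lon + rng.normal(0.0, cfg.shelter_jitter_deg)
                    lat = shelter_lat + rng.normal(0.0, cfg.shelter_jitter_deg)
                elif state != STATE_INACTIVE:
                    lon = shelter_lon + rng.normal(0.0, cfg.shelter_active_scatter_deg)
                    lat = shelter_lat + rng.normal(0.0, cfg.shelter_active_scatter_deg)
            elif prev_t is not None:
                dt_h = min((ft - prev_t) / pd.Timedelta(hours=1), cfg.gap_dt_cap_h)
                mean_v, shape, centre, rho = cfg.state_kinematics[state]
                speed = rng.gamma(shape, mean_v / shape)
                turn = _wrapped_cauchy(rng, centre, rho)
                heading = np.mod(heading + turn, 2.0 * np.pi)
                # soft tether: outside the home range, head back with noise
                if haversine_km(lon, lat, home_lon, home_lat) > cfg.tether_km:
                    from .kinematics import initial_bearing_rad
                    back = float(initial_bearing_rad(lon, lat, home_lon, home_lat))
                    heading = np.mod(back + rng.normal(0.0, 0.3), 2.0 * np.pi)
                lon, lat = _advance(lon, lat, heading, speed * dt_h)
            prev_t = ft
            was_sheltering = sheltering
            fixes.append({"individual_id": ind, "t": ft, "lon": lon, "lat": lat})
            truth.append({"individual_id": ind, "t": ft, "lon": lon, "lat": lat,
                          "state4": state, "active": int(state != STATE_INACTIVE),
                          "absentee": absentee})
    return pd.DataFrame(fixes), pd.DataFrame(truth)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - np.nanmean(x)) / np.nanstd(x, ddof=1)


def simulate_regression_data(n: int, beta: tuple = (0.6, 0.25, -0.20),
                             rho: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Bernoulli state draws on standardized correlated weather covariates.

    Covariates (z_bp, z_wv) are standard normal with correlation ``rho``;
    P(active) = inv-logit(b0 + b_bp z_bp + b_wv z_wv).  Used for the
    coefficient-recovery study at its planted truth.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    Z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    eta = beta[0] + beta[1] * Z[:, 0] + beta[2] * Z[:, 1]
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=n) < p).astype(int)
    return pd.DataFrame({"state2": y, "bp_kpa": Z[:, 0], "wv_kmh": Z[:, 1]})


def separable_features(n_per_state: int = 500, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """The documented well-separated four-quadrant (speed, turn) scenario.

    Low/high speeds centred at 0.3 vs 20 km/h, low/high turns at 0.2 vs
    2.5 rad; 500 points per state by default.  Returns (features, labels)
    with labels in state-code order LL, LH, HL, HH.
    """
    rng = np.random.default_rng(seed)
    centres = {0: (0.3, 0.2), 1: (0.3, 2.5), 2: (20.0, 0.2), 3: (20.0, 2.5)}
    sds = {0: (0.15, 0.1), 1: (0.15, 0.25), 2: (3.0, 0.1), 3: (3.0, 0.25)}
    X, y = [], []
    for k in range(4):
        sp = np.abs(rng.normal(centres[k][0], sds[k][0], size=n_per_state))
        tu = np.clip(rng.normal(centres[k][1], sds[k][1], size=n_per_state), 0.0, np.pi)
        X.append(np.column_stack([sp, tu]))
        y.append(np.full(n_per_state, k))
    return np.vstack(X), np.concatenate(y)


def recovery_report(truth: pd.DataFrame, predicted_state4: pd.Series | np.ndarray,
                    retained_ids: list[str] | None = None,
                    beta_hat: dict | None = None,
                    window_recovered: tuple | None = None,
                    window_truth: tuple | None = None) -> dict:
    """Compare pipeline outputs against generator ground truth.

    Reports 4-state and pooled confusion matrices and agreement rates,
    exclusion-count correctness, coefficient errors when ``beta_hat`` is
    given as {name: (estimate, planted)}, and window-bound exactness.
    """
    pred = np.asarray(predicted_state4)
    true4 = truth["state4"].to_numpy()[:len(pred)]
    cm4 = np.zeros((4, 4), dtype=int)
    for a, b in zip(true4, pred):
        cm4[a, b] += 1
    pooled_true = (true4 != 0).astype(int)
    pooled_pred = (pred != 0).astype(int)
    cm2 = np.zeros((2, 2), dtype=int)
    for a, b in zip(pooled_true, pooled_pred):
        cm2[a, b] += 1
    out = {
        "confusion_4state": cm4,
        "confusion_pooled": cm2,
        "agreement_4state": float(np.mean(true4 == pred)),
        "agreement_pooled": float(np.mean(pooled_true == pooled_pred)),
    }
    if retained_ids is not None and "absentee" in truth:
        per_ind = truth.drop_duplicates("individual_id")
        present = set(per_ind.loc[~per_ind["absentee"], "individual_id"])
        out["n_retained"] = len(retained_ids)
        out["n_expected_retained"] = len(present)
        out["exclusions_correct"] = set(retained_ids) == present
    if beta_hat:
        out["beta_errors"] = {k: float(est - tru) for k, (est, tru) in beta_hat.items()}
    if window_recovered is not None and window_truth is not None:
        out["window_exact"] = (pd.Timestamp(window_recovered[0]) == pd.Timestamp(window_truth[0])
                               and pd.Timestamp(window_recovered[1]) == pd.Timestamp(window_truth[1]))
    return out


def irma_like_scenario(seed: int = 0) -> tuple[MetSimConfig, MoveSimConfig]:
    """The default study scenario: one mid-month cyclone, 40 birds of whom
    8 are planted absentees (echoing a 32-bird analyzed cohort)."""
    return (MetSimConfig(seed=seed),
            MoveSimConfig(seed=seed + 1))
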