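"""End-to-end orchestration: ingest -> core range -> EMbC -> window -> model.

``run_event`` executes the full single-event analysis and returns all
stage artifacts in memory (optionally writing them under an output
directory); ``run_multi_event`` adds the between-event nonparametric
comparisons with letter groupings.  Runs are deterministic for a fixed
config and seed, and every analysis default follows the study protocol
(speed filter 65 km/h, core range at the 25 % UD on a 400-cell grid with
0.4 deg padding, 1-SD pressure-anomaly rule, smoothing weight 2,
standardized covariates).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import core_range as cr
from . import embc as embc_mod
from . import io as sio
from . import kinematics as kin
from . import state_model as sm
from . import stormwin as sw

__all__ = ["RunConfig", "run_event", "run_multi_event", "letter_groups"]


@dataclass
class RunConfig:
    """All parameters of one event run; round-trips through YAML."""

    event_name: str = "event"
    tracks_path: str | None = None
    weather_path: str | None = None
    landfall: str | None = None          # ISO timestamp hint for the cyclone run
    vmax_kmh: float = 65.0
    max_gap_h: float = 6.0
    ud_level: float = 0.25
    grid_n: int = 400
    extent_pad_deg: float = 0.4
    smoothing_w: float = 2.0
    anomaly_side: str = "two"
    standardize: bool = True
    pressure_unit: str = "hPa"
    wind_unit: str = "km/h"
    tracks_schema: dict | None = None    # column remapping for read_tracks
    weather_schema: dict | None = None   # column remapping for read_station
    seed: int = 0
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_event(cfg: RunConfig, fixes_by_id: dict | None = None,
              station: sio.StationSeries | None = None) -> dict:
    """Run the single-event pipeline; inputs may be in-memory or file paths.

    Returns a dict of stage artifacts: QC logs, per-fix feature/label
    table, core range, study window, the four model fits with AIC ranking,
    odds ratios of the AIC-best model, and the two report tables.
    """
    if fixes_by_id is None:
        if cfg.tracks_path is None:
            raise ValueError("either in-memory fixes or tracks_path required")
        fixes_by_id, ingest_report = sio.read_tracks(cfg.tracks_path,
                                                     schema=cfg.tracks_schema)
    else:
        ingest_report = None
    if station is None:
        if cfg.weather_path is None:
            raise ValueError("either in-memory station series or weather_path required")
        station = sio.read_station(cfg.weather_path, pressure_unit=cfg.pressure_unit,
                                   wind_unit=cfg.wind_unit, schema=cfg.weather_schema)

    # --- QC and burst structure -----------------------------------------
    removed_log = []
    clean: dict[str, pd.DataFrame] = {}
    for ind, df in fixes_by_id.items():
        kept, removed = sio.speed_filter(df, vmax=cfg.vmax_kmh)
        if len(removed):
            removed_log.append(removed.assign(individual_id=ind))
        if len(kept) >= 3:
            clean[ind] = sio.split_bursts(kept, max_gap_h=cfg.max_gap_h)

    # --- weather, anomalies, study window --------------------------------
    stats = sw.monthly_stats(station)
    runs = sw.detect_anomalies(station, side=cfg.anomaly_side)
    window = sw.study_window(runs, station, cyclone_hint=cfg.landfall)
    landfall = (pd.Timestamp(cfg.landfall) if cfg.landfall
                else window.cyclone_run.start_t)

    # --- core range on the pooled monthly fixes --------------------------
    pooled = pd.concat(clean.values(), ignore_index=True)
    ud = cr.CoreRangeKDE(level=cfg.ud_level, grid_n=cfg.grid_n,
                         extent_pad=cfg.extent_pad_deg,
                         random_state=cfg.seed).fit(pooled[["lon", "lat"]].to_numpy())
    retained, exclusion_log = cr.restrict_to_core(
        clean, ud.core_, landfall, window=(window.start_t, window.end_t))
    analysed = {i: clean[i] for i in retained}
    if not analysed:
        raise RuntimeError("no individuals retained after core-range restriction")

    # --- per-step features ------------------------------------------------
    feat_frames = []
    for ind, df in analysed.items():
        for bid, burst in df.groupby("burst_id"):
            if len(burst) < 2:
                continue
            steps = kin.step_metrics(burst)
            f = burst.iloc[1:][["individual_id", "t", "lon", "lat"]].reset_index(drop=True)
            f["burst_id"] = bid
            f["speed_kmh"] = steps["speed_kmh"].to_numpy()
            f["turn_rad"] = steps["turn_rad"].to_numpy()
            feat_frames.append(f)
    features = pd.concat(feat_frames, ignore_index=True)

    # --- EMbC, smoothing, pooling ----------------------------------------
    X = features[["speed_kmh", "turn_rad"]].to_numpy()
    model = embc_mod.EMbC(smoothing_weight=cfg.smoothing_w,
                          random_state=cfg.seed).fit(X)
    seq = model.label(X)
    burst_key = (features["individual_id"].astype(str) + "/"
                 + features["burst_id"].astype(str)).to_numpy()
    _, burst_codes = np.unique(burst_key, return_inverse=True)
    smoothed = embc_mod.smooth_labels(seq, w=cfg.smoothing_w, burst_ids=burst_codes)
    features["state4"] = smoothed.labels
    features["state2"] = smoothed.pooled

    budget = embc_mod.activity_budget(
        {ind: g["state2"].to_numpy() for ind, g in features.groupby("individual_id")})

    # --- window subset, weather matching, regression ----------------------
    inwin = features.loc[window.contains(features["t"])].reset_index(drop=True)
    matched = sw.match_weather(inwin, station)
    fits = sm.model_set(matched, state_col="state2", standardize=cfg.standardize)
    ranking = sm.aic_select(fits)
    best_name = ranking["model"].iloc[0]
    best = fits[best_name]
    odds = {c: {"per_unit_increase": sm.odds_ratio(best, c, "per-unit-increase"),
                "per_unit_decrease": sm.odds_ratio(best, c, "per-unit-decrease")}
            for c in best.covariates}

    movement = _movement_table(analysed)

    report = {
        "event": cfg.event_name,
        "config_digest": cfg.digest(),
        "ingest_report": ingest_report,
        "speed_filter_removed": (pd.concat(removed_log, ignore_index=True)
                                 if removed_log else pd.DataFrame()),
        "monthly_stats": stats,
        "anomaly_runs": runs,
        "study_window": window,
        "core_range": ud,
        "retained_ids": retained,
        "exclusion_log": exclusion_log,
        "features": features,
        "embc_model": model,
        "activity_budget": budget,
        "movement_summary": movement,
        "matched": matched,
        "fits": fits,
        "aic_ranking": ranking,
        "best_model": best_name,
        "odds_ratios": odds,
        "table1_row": sw.window_report_row(cfg.event_name, station, window,
                                           n_locations=len(matched)),
        "table2": sm.coefficient_table({cfg.event_name: fits["global"]}),
        "station": station,
    }
    if cfg.out_dir:
        _write_artifacts(cfg, report)
    return report


def _movement_table(analysed: dict[str, pd.DataFrame]) -> pd.DataFrame:
    steps_by, fixes_by = {}, {}
    for ind, df in analysed.items():
        parts = [kin.step_metrics(b) for _, b in df.groupby("burst_id") if len(b) >= 2]
        steps_by[ind] = (pd.concat(parts, ignore_index=True)
                         if parts else pd.DataFrame(columns=["step_km"]))
        fixes_by[ind] = df
    return kin.movement_summary(steps_by, fixes_by)


def _write_artifacts(cfg: RunConfig, report: dict) -> None:
    import pathlib

    out = pathlib.Path(cfg.out_dir)
    (out / "reports").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    (out / "logs").mkdir(exist_ok=True)
    report["features"].to_csv(out / "reports" / "labels.csv", index=False)
    report["exclusion_log"].to_csv(out / "reports" / "exclusions.csv", index=False)
    report["aic_ranking"].to_csv(out / "reports" / "aic.csv", index=False)
    report["table2"].to_csv(out / "reports" / "coefficients.csv", index=False)
    pd.DataFrame([report["table1_row"]]).to_csv(out / "reports" / "meteorology.csv",
                                                index=False)
    report["activity_budget"].to_csv(out / "reports" / "activity_budget.csv",
                                     index=False)
    with open(out / "reports" / "core_range.geojson", "w") as fh:
        fh.write(cr.core_polygons_geojson(report["core_range"].core_))
    embc_mod.plot_state_scatter(report["embc_model"],
                                report["features"][["speed_kmh", "turn_rad"]].to_numpy(),
                                report["features"]["state4"].to_numpy(),
                                out / "figures" / "state_scatter.png")
    sw.plot_weather_series({cfg.event_name: report["station"]},
                           out / "figures" / "weather.png")
    prov = {"event": cfg.event_name, "config_digest": report["config_digest"],
            "seed": cfg.seed, "n_retained": len(report["retained_ids"]),
            "best_model": report["best_model"]}
    with open(out / "logs" / "run.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)


def letter_groups(names: list[str], differ: dict[tuple, bool]) -> dict[str, str]:
    """Compact letter display: events that never differ significantly share
    a letter; significantly different events get distinct letters."""
    letters: list[list[str]] = []
    for name in names:
        placed = False
        for grp in letters:
            if all(not differ.get(tuple(sorted((name, other))), False) for other in grp):
                grp.append(name)
                placed = True
                break
        if not placed:
            letters.append([name])
    out = {}
    for i, grp in enumerate(letters):
        for name in grp:
            out[name] = chr(ord("a") + i)
    return out


def run_multi_event(reports: list[dict], alpha: float = 0.05,
                    holm: bool = False) -> dict:
    """Between-event comparison of in-window pressure and wind.

    Kruskal-Wallis across events; pairwise Wilcoxon rank-sum follow-ups
    when the omnibus test is significant (raw p-values by default, Holm
    adjustment optional); letter groups per variable.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 event runs")
    names = [r["event"] for r in reports]
    out: dict = {"events": names}
    for var in ("bp_kpa", "wv_kmh"):
        samples = []
        for r in reports:
            win = r["study_window"]
            s = r["station"].in_window(win.start_t, win.end_t)[var].dropna().to_numpy()
            samples.append(s)
        kw = sm.kruskal_wallis(*samples)
        pair: dict[tuple, sm.TestResult] = {}
        differ: dict[tuple, bool] = {}
        if kw.p_value < alpha:
            keys = []
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    res = sm.wilcoxon_ranksum(samples[i], samples[j])
                    key = tuple(sorted((names[i], names[j])))
                    pair[key] = res
                    keys.append(key)
            pvals = [pair[k].p_value for k in keys]
            if holm:
                order = np.argsort(pvals)
                m = len(pvals)
                adj = {}
                running = 0.0
                for rank, oi in enumerate(order):
                    running = max(running, (m - rank) * pvals[oi])
                    adj[keys[oi]] = min(running, 1.0)
                for k in keys:
                    differ[k] = adj[k] < alpha
            else:
                for k in keys:
                    differ[k] = pair[k].p_value < alpha
        out[var] = {"kruskal_wallis": kw, "pairwise": pair,
                    "letters": letter_groups(names, differ)}
    return out
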