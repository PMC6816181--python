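"""Monthly statistics, anomaly runs, study window, weather matching."""

import numpy as np
import pandas as pd
import pytest

from stormbird.io import StationSeries
from stormbird.stormwin import (detect_anomalies, match_weather, monthly_stats,
                                study_window, window_report_row)


def make_series(bp, wv=None, start="2017-09-01"):
    bp = np.asarray(bp, dtype=float)
    t = pd.date_range(start, periods=len(bp), freq="h")
    wv = np.full(len(bp), 10.0) if wv is None else np.asarray(wv, dtype=float)
    return StationSeries(station_id="TST", month=pd.Timestamp(start).strftime("%Y-%m"),
                         data=pd.DataFrame({"t": t, "bp_kpa": bp, "wv_kmh": wv}))


class TestMonthlyStats:
    def test_constant_series(self):
        s = monthly_stats(make_series(np.full(48, 101.0)))
        assert s["bp_mean_kpa"] == 101.0 and s["bp_sd_kpa"] == 0.0

    def test_two_readings_hand_arithmetic(self):
        s = monthly_stats(make_series([100.0, 102.0]))
        assert s["bp_mean_kpa"] == 101.0
        assert np.isclose(s["bp_sd_kpa"], np.sqrt(2.0))

    def test_missing_hours_skipped(self):
        bp = np.full(48, 101.0)
        bp[10:20] = np.nan
        s = monthly_stats(make_series(bp))
        assert s["bp_mean_kpa"] == 101.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            monthly_stats(make_series(np.full(48, np.nan)))

    def test_synthetic_month_matches_generator_scale(self, synth_weather):
        station, _ = synth_weather
        s = monthly_stats(station)
        assert 101.0 < s["bp_mean_kpa"] < 101.6    # baseline 101.4 minus dips
        assert 0.2 < s["bp_sd_kpa"] < 0.6
        assert s["bp_min_kpa"] < 100.0             # ~1.8 kPa cyclone dip


class TestDetectAnomalies:
    def test_flat_series_no_runs(self):
        runs = detect_anomalies(make_series(np.full(100, 101.0)), mean=101.0, sd=0.3)
        assert runs == []

    def test_hand_built_single_run(self):
        bp = np.full(200, 101.3)
        bp[100:111] = 100.8                       # |dev| = 0.5 >= sd
        runs = detect_anomalies(make_series(bp), mean=101.3, sd=0.3)
        assert len(runs) == 1
        t0 = pd.Timestamp("2017-09-01")
        assert runs[0].start_t == t0 + pd.Timedelta(hours=100)
        assert runs[0].end_t == t0 + pd.Timedelta(hours=110)
        assert runs[0].extreme_kpa == 100.8

    def test_boundary_reading_is_anomalous(self):
        bp = np.full(50, 101.25)
        bp[25] = 101.0                            # exactly mean - sd
        runs = detect_anomalies(make_series(bp), mean=101.25, sd=0.25)
        assert len(runs) == 1 and runs[0].n_hours == 1

    def test_two_sided_default_and_low_side_option(self):
        bp = np.full(50, 101.3)
        bp[10] = 101.9                            # high-side anomaly
        series = make_series(bp)
        assert len(detect_anomalies(series, mean=101.3, sd=0.3)) == 1
        assert detect_anomalies(series, mean=101.3, sd=0.3, side="low") == []

    def test_gap_breaks_runs(self):
        bp = np.full(50, 101.3)
        bp[10:12] = 100.8
        bp[12] = np.nan
        bp[13:15] = 100.8
        runs = detect_anomalies(make_series(bp), mean=101.3, sd=0.3)
        assert len(runs) == 2

    def test_reconstruction_stability(self, synth_weather):
        station, _ = synth_weather
        stats = monthly_stats(station)
        runs = detect_anomalies(station)
        flagged = np.zeros(len(station.data), dtype=bool)
        t0 = station.data["t"].iloc[0]
        for r in runs:
            i = int((r.start_t - t0) / pd.Timedelta(hours=1))
            j = int((r.end_t - t0) / pd.Timedelta(hours=1))
            flagged[i:j + 1] = True
        masked = station.data.copy()
        masked.loc[~flagged, "bp_kpa"] = np.nan
        series2 = StationSeries("TST", masked, station.month)
        runs2 = detect_anomalies(series2, mean=stats["bp_mean_kpa"],
                                 sd=stats["bp_sd_kpa"])
        assert [(r.start_t, r.end_t) for r in runs2] == \
               [(r.start_t, r.end_t) for r in runs]


class TestStudyWindow:
    def _three_run_series(self):
        # runs at day 3, days 10-11 (contains the minimum), day 25
        bp = np.full(30 * 24, 101.3)
        bp[2 * 24:2 * 24 + 6] = 100.8
        bp[9 * 24:11 * 24] = 100.5
        bp[10 * 24] = 99.6                       # monthly minimum
        bp[24 * 24:24 * 24 + 6] = 100.9
        return make_series(bp)

    def test_hand_trace_of_bracketing_rule(self):
        series = self._three_run_series()
        runs = detect_anomalies(series, mean=101.3, sd=0.3)
        assert len(runs) == 3
        win = study_window(runs, series)
        t0 = pd.Timestamp("2017-09-01")
        assert win.start_t == t0 + pd.Timedelta(hours=2 * 24 + 5)    # end of pre-run
        assert win.end_t == t0 + pd.Timedelta(hours=24 * 24)         # start of post-run
        assert win.cyclone_run.start_t == t0 + pd.Timedelta(hours=9 * 24)
        assert win.contains(win.cyclone_run.start_t)

    def test_single_run_spans_month(self):
        bp = np.full(30 * 24, 101.3)
        bp[9 * 24:10 * 24] = 100.0
        series = make_series(bp)
        runs = detect_anomalies(series, mean=101.3, sd=0.3)
        win = study_window(runs, series)
        assert win.start_t == series.data["t"].iloc[0]
        assert win.end_t == series.data["t"].iloc[-1]

    def test_cyclone_hint_overrides_minimum(self):
        series = self._three_run_series()
        runs = detect_anomalies(series, mean=101.3, sd=0.3)
        win = study_window(runs, series, cyclone_hint="2017-09-03 02:00")
        assert win.cyclone_run.start_t == pd.Timestamp("2017-09-03 00:00")

    def test_bad_hint_lists_candidates(self):
        series = self._three_run_series()
        runs = detect_anomalies(series, mean=101.3, sd=0.3)
        with pytest.raises(ValueError, match="candidates"):
            study_window(runs, series, cyclone_hint="2017-09-07 00:00")

    def test_raising_sd_never_shrinks_window(self, synth_weather):
        station, _ = synth_weather
        stats = monthly_stats(station)
        prev = None
        for mult in (1.0, 1.2, 1.5):
            runs = detect_anomalies(station, mean=stats["bp_mean_kpa"],
                                    sd=stats["bp_sd_kpa"] * mult)
            win = study_window(runs, station)
            if prev is not None:
                assert win.start_t <= prev[0] and win.end_t >= prev[1]
            prev = (win.start_t, win.end_t)


class TestMatchWeather:
    def _fixes(self, minutes):
        t0 = pd.Timestamp("2017-09-01")
        return pd.DataFrame({"individual_id": "A",
                             "t": [t0 + pd.Timedelta(minutes=m) for m in minutes]})

    def test_nearest_record_wins(self):
        series = make_series(np.full(24, 101.0))
        out = match_weather(self._fixes([12 * 60 + 40]), series)
        assert out["weather_t"].iloc[0] == pd.Timestamp("2017-09-01 13:00")

    def test_midpoint_tie_goes_earlier(self):
        series = make_series(np.full(24, 101.0))
        out = match_weather(self._fixes([12 * 60 + 30]), series)
        assert out["weather_t"].iloc[0] == pd.Timestamp("2017-09-01 12:00")

    def test_far_fixes_dropped_with_warning(self):
        bp = np.full(24, np.nan)
        bp[0] = 101.0
        series = make_series(bp, wv=np.full(24, np.nan))
        series.data.loc[0, "wv_kmh"] = 5.0
        with pytest.warns(UserWarning, match="dropped"):
            out = match_weather(self._fixes([0, 300]), series)
        assert len(out) == 1

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(20)
        series = make_series(101.0 + rng.normal(0, 0.1, 72))
        minutes = rng.uniform(0, 71 * 60, size=50)
        out = match_weather(self._fixes(minutes), series)
        wt = series.data["t"].to_numpy()
        for m, got in zip(minutes, out["weather_t"]):
            ft = np.datetime64(pd.Timestamp("2017-09-01") + pd.Timedelta(minutes=m))
            deltas = np.abs((wt - ft).astype("timedelta64[s]").astype(float))
            best = deltas.min()
            # earliest record achieving the minimum
            expect = wt[np.flatnonzero(deltas == best)[0]]
            assert np.datetime64(got) == expect
        assert (out["dt_min"] <= 90.0).all()


def test_report_row_schema(synth_weather):
    station, _ = synth_weather
    runs = detect_anomalies(station)
    win = study_window(runs, station)
    row = window_report_row("Irma-like", station, win, n_locations=123)
    assert list(row) == ["cyclone", "bp_monthly_mean_kpa", "bp_monthly_sd_kpa",
                         "bp_minimum_kpa", "wv_monthly_mean_kmh",
                         "wv_monthly_sd_kmh", "wv_maximum_kmh", "study_period",
                         "locations_n"]
    assert row["locations_n"] == 123
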