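import io as _io

import numpy as np
import pandas as pd
import pytest

from stormbird.synthetic import MetSimConfig, MoveSimConfig, simulate_tracks, simulate_weather


def make_track(times_h, lons, lats, ind="A"):
    """Build a fix DataFrame from hour offsets and coordinates."""
    t0 = pd.Timestamp("2017-09-01 00:00")
    return pd.DataFrame({
        "individual_id": ind,
        "t": [t0 + pd.Timedelta(hours=float(h)) for h in times_h],
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
    })


def csv_handle(text: str):
    return _io.StringIO(text)


@pytest.fixture(scope="session")
def synth_weather():
    return simulate_weather(MetSimConfig(seed=11))


@pytest.fixture(scope="session")
def synth_bundle(synth_weather):
    station, wx_truth = synth_weather
    fixes, truth = simulate_tracks(MoveSimConfig(seed=12), station)
    return station, wx_truth, fixes, truth
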