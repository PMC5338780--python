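import numpy as np
import pandas as pd
import pytest

import foragespec as fs

COLONY = (-49.4333, 70.4333)


def make_deployment(offsets_km, dt_s=60.0, colony=COLONY, individual="B00",
                    stage="chick_rearing"):
    """Deployment from planar (east, north) km offsets at a fixed cadence."""
    x = np.array([p[0] for p in offsets_km], float)
    y = np.array([p[1] for p in offsets_km], float)
    lat, lon = fs.tracks.unproject_local_km(x, y, colony)
    t0 = pd.Timestamp("2015-01-10T06:00:00")
    times = [t0 + pd.Timedelta(seconds=i * dt_s) for i in range(len(x))]
    return fs.Deployment(individual_id=individual, stage=stage, colony=colony,
                         fixes=pd.DataFrame({"time": times, "lat": lat, "lon": lon}))


def make_depth_series(depths, dt_s=1.0, individual="B00"):
    t0 = pd.Timestamp("2015-01-10T06:00:00")
    times = pd.Series([t0 + pd.Timedelta(seconds=i * dt_s) for i in range(len(depths))])
    return fs.DepthSeries(individual_id=individual, times=times,
                          depth_m=np.asarray(depths, float))


@pytest.fixture(scope="session")
def colony():
    return COLONY


@pytest.fixture(scope="session")
def small_population():
    """One small simulated colony shared by read-only tests."""
    cfg = fs.SimConfig(seed=42, n_individuals=5, trips_per_individual=(4, 6),
                       mean_trip_distance_km=4.0, dives_per_trip=6)
    deployments, depth_frames, iso, diets, truth = fs.simulate_population(cfg)
    return cfg, deployments, depth_frames, iso, diets, truth
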