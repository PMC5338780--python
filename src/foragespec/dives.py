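"""Dive detection from 1-Hz time-depth records and dive georeferencing.

A dive is a maximal excursion of (zero-offset-corrected) depth beyond a
threshold, extended to the bracketing threshold crossings by linear
interpolation in time.  Per-dive metrics are maximum depth, duration between
crossings, and the summed absolute vertical distance travelled within the
dive (descent + ascent + wiggles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateDiveError, InvalidInputError
from .tracks import Trip

logger = logging.getLogger(__name__)


@dataclass
class DepthSeries:
    """A depth record for one individual: times (nominally 1 s apart) and
    depth in metres, positive down."""

    individual_id: str
    times: pd.Series
    depth_m: np.ndarray

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, float)
        if len(self.times) != len(self.depth_m):
            raise InvalidInputError("times and depths differ in length")
        t = self.times.to_numpy().astype("datetime64[ns]").astype(np.int64)
        if len(t) >= 2 and not (np.diff(t) > 0).all():
            raise InvalidInputError("depth record times must be strictly increasing")

    @property
    def t_seconds(self) -> np.ndarray:
        return self.times.to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9


@dataclass
class DiveEvent:
    """One submergence beyond the dive threshold."""

    individual_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    max_depth_m: float
    duration_s: float
    vertical_distance_m: float
    lat: float | None = None
    lon: float | None = None
    georeferenced: bool = False


def zero_offset_correct(series: DepthSeries, window_s: float = 600.0,
                        quantile: float = 0.05) -> DepthSeries:
    """Remove surface-pressure drift with a rolling lower-quantile baseline.

    The baseline is the centred rolling ``quantile`` of depth over
    ``window_s``; subtracting it recentres surface intervals on zero.  Records
    shorter than the window are returned uncorrected with a log notice.
    """
    t = series.t_seconds
    if t[-1] - t[0] < window_s:
        logger.info("record for %s shorter than correction window; skipped",
                    series.individual_id)
        return series
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    win = max(3, int(round(window_s / dt)))
    baseline = (pd.Series(series.depth_m)
                .rolling(win, center=True, min_periods=max(3, win // 4))
                .quantile(quantile)
                .to_numpy())
    corrected = series.depth_m - baseline
    if (corrected < -0.5).any():
        logger.warning("zero-offset correction pushed %d samples below -0.5 m for %s",
                       int((corrected < -0.5).sum()), series.individual_id)
    return replace(series, depth_m=corrected)


def _crossing_time(t0: float, d0: float, t1: float, d1: float, thr: float) -> float:
    """Time at which depth crosses ``thr`` on the segment (t0,d0)-(t1,d1)."""
    if d1 == d0:
        return t0
    return t0 + (thr - d0) * (t1 - t0) / (d1 - d0)


def dive_metrics(depths: np.ndarray) -> tuple[float, float, float]:
    """(max_depth, duration placeholder, vertical distance) for one dive's samples.

    ``vertical_distance`` is the integrated absolute depth change within the
    dive; duration is returned as the sample span and is normally replaced by
    the threshold-crossing span computed in :func:`detect_dives`.
    """
    depths = np.asarray(depths, float)
    if len(depths) < 2:
        raise DegenerateDiveError("a dive needs at least two samples")
    vertical = float(np.sum(np.abs(np.diff(depths))))
    return float(np.max(depths)), float(len(depths) - 1), vertical


def detect_dives(series: DepthSeries, threshold_m: float = 1.0,
                 min_duration_s: float = 2.0) -> list[DiveEvent]:
    """Detect dives as maximal runs with depth strictly above ``threshold_m``.

    Start and end are the bracketing threshold crossings, linearly
    interpolated in time; the crossing points (at exactly the threshold depth)
    also bound the vertical-distance integral, so every dive satisfies
    ``vertical_distance >= 2 * (max_depth - threshold)``.  Sub-second spikes
    shorter than ``min_duration_s`` between crossings are discarded as sensor
    noise.
    """
    d = series.depth_m
    t = series.t_seconds
    wet = d > threshold_m
    if not wet.any():
        return []
    events: list[DiveEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], wet.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        last = stop - 1
        if start > 0:
            t_start = _crossing_time(t[start - 1], d[start - 1], t[start], d[start], threshold_m)
        else:
            t_start = t[0]
        if stop < len(d):
            t_end = _crossing_time(t[last], d[last], t[stop], d[stop], threshold_m)
        else:
            t_end = t[-1]
        seg = d[start:stop]
        # virtual samples at the crossings bound the vertical integral
        prof = np.concatenate(([threshold_m] if start > 0 else [],
                               seg,
                               [threshold_m] if stop < len(d) else []))
        if len(prof) < 2:
            prof = np.concatenate((prof, prof))
        max_depth, _, vertical = dive_metrics(prof)
        if t_end - t_start < min_duration_s:
            continue
        events.append(DiveEvent(
            individual_id=series.individual_id,
            start=pd.Timestamp(round(t_start * 1e9), unit="ns"),
            end=pd.Timestamp(round(t_end * 1e9), unit="ns"),
            max_depth_m=max_depth,
            duration_s=float(t_end - t_start),
            vertical_distance_m=vertical,
        ))
    return events


def georeference_dives(dives: list[DiveEvent], trip: Trip) -> list[DiveEvent]:
    """Attach the interpolated track position at each dive's start time.

    Dives starting outside the track's time coverage are flagged
    ungeoreferenced.  The surface position just before descent is used; birds
    move little horizontally while submerged.
    """
    fx = trip.fixes
    t = fx["time"].to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
    lat = fx["lat"].to_numpy(float)
    lon = fx["lon"].to_numpy(float)
    out: list[DiveEvent] = []
    n_hit = 0
    for dv in dives:
        ts = dv.start.value / 1e9
        if t[0] <= ts <= t[-1]:
            out.append(replace(dv, lat=float(np.interp(ts, t, lat)),
                               lon=float(np.interp(ts, t, lon)), georeferenced=True))
            n_hit += 1
        else:
            out.append(replace(dv, lat=None, lon=None, georeferenced=False))
    if dives and n_hit == 0:
        logger.warning("no temporal overlap between dives and trip %s/%d",
                       trip.individual_id, trip.trip_index)
    return out


def dives_to_frame(dives: list[DiveEvent]) -> pd.DataFrame:
    """One row per dive, suitable for the dives CSV writer."""
    return pd.DataFrame([{
        "individual_id": d.individual_id,
        "start": d.start,
        "end": d.end,
        "max_depth_m": d.max_depth_m,
        "duration_s": d.duration_s,
        "vertical_distance_m": d.vertical_distance_m,
        "lat": d.lat,
        "lon": d.lon,
        "georeferenced": d.georeferenced,
    } for d in dives])
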