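"""GPS track cleaning, central-place trip segmentation and per-trip spatial metrics.

The raw movement record for one logger deployment is a time-ordered table of
fixes (UTC timestamp, latitude, longitude).  Processing proceeds
speed-filter -> trip segmentation -> (optional) linear interpolation ->
trip metrics -> grid-cell rasterization.  Distances are great-circle on a
sphere of radius 6371 km; gridding uses a colony-anchored equirectangular
projection, adequate for coastal foraging ranges of a few tens of km.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedBearingError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: km per degree of latitude / of longitude at the equator (equirectangular grid)
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON = 111.320

FIX_COLUMNS = ("time", "lat", "lon")


@dataclass
class Deployment:
    """One logger deployment: an individual at a breeding stage with ordered fixes.

    ``fixes`` is a DataFrame with columns ``time`` (tz-aware or naive UTC
    Timestamp), ``lat``, ``lon`` (decimal degrees WGS84), strictly increasing
    in time.
    """

    individual_id: str
    stage: str
    colony: tuple[float, float]
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FIX_COLUMNS if c not in self.fixes.columns]
        if missing:
            raise InvalidInputError(f"fix table missing columns {missing}")
        lat = self.fixes["lat"].to_numpy(float)
        lon = self.fixes["lon"].to_numpy(float)
        if not (np.isfinite(lat).all() and np.isfinite(lon).all()):
            raise InvalidInputError("non-finite coordinates in fixes")
        if (np.abs(lat) > 90).any() or (lon <= -180).any() or (lon > 180).any():
            raise InvalidInputError("coordinates outside WGS84 bounds")
        t = self.fixes["time"].to_numpy()
        if len(t) >= 2 and not (np.diff(t.astype("datetime64[ns]").astype(np.int64)) > 0).all():
            raise InvalidInputError("fix times must be strictly increasing")


@dataclass
class Trip:
    """A colony-to-colony excursion with derived metrics.

    Metric fields are ``nan`` until :func:`trip_metrics` populates them;
    ``cells`` is empty until :func:`rasterize_trip` runs.
    """

    individual_id: str
    stage: str
    trip_index: int
    fixes: pd.DataFrame
    duration_h: float = math.nan
    max_distance_km: float = math.nan
    total_distance_km: float = math.nan
    heading_deg: float = math.nan
    cells: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    cell_size_km: float = math.nan


def _check_coords(*points: tuple[float, float]) -> None:
    for p in points:
        if not (math.isfinite(p[0]) and math.isfinite(p[1])):
            raise InvalidInputError(f"non-finite coordinate {p!r}")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points."""
    _check_coords(a, b)
    phi1, lam1, phi2, lam2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def haversine_km_vec(lat1, lon1, lat2, lon2):
    """Vectorised haversine; inputs in decimal degrees, output km."""
    phi1, lam1, phi2, lam2 = map(np.radians, (np.asarray(lat1, float), np.asarray(lon1, float),
                                              np.asarray(lat2, float), np.asarray(lon2, float)))
    h = (np.sin((phi2 - phi1) / 2) ** 2
         + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def wrap_deg(angle: float) -> float:
    """Map an angle in degrees to the (-180, 180] convention."""
    a = math.fmod(angle, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def initial_bearing_deg(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Initial great-circle bearing from ``a`` to ``b``, clockwise from true
    north, in (-180, 180]."""
    _check_coords(a, b)
    if a == b:
        raise UndefinedBearingError("bearing undefined between coincident points")
    phi1, lam1, phi2, lam2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    dlam = lam2 - lam1
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return wrap_deg(math.degrees(math.atan2(y, x)))


def speed_filter(deployment: Deployment, vmax_mps: float = 18.0) -> Deployment:
    """Remove fixes implying travel speed above ``vmax_mps``.

    A single forward pass: each fix is tested against the *last retained* fix;
    fixes whose implied speed exceeds the threshold are dropped.  The first
    fix is always retained.  Idempotent by construction.
    """
    fx = deployment.fixes.reset_index(drop=True)
    if len(fx) < 2 or not math.isfinite(vmax_mps):
        return replace(deployment, fixes=fx)
    t = fx["time"].to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
    lat = fx["lat"].to_numpy(float)
    lon = fx["lon"].to_numpy(float)
    keep = [0]
    for i in range(1, len(fx)):
        j = keep[-1]
        dt = t[i] - t[j]
        dist_m = haversine_km(( lat[j], lon[j]), (lat[i], lon[i])) * 1000.0
        if dt > 0 and dist_m / dt <= vmax_mps:
            keep.append(i)
    if len(keep) == 1:
        logger.warning("speed filter removed all but the first fix for %s",
                       deployment.individual_id)
    return replace(deployment, fixes=fx.iloc[keep].reset_index(drop=True))


def segment_trips(deployment: Deployment,
                  colony_radius_km: float = 0.2,
                  min_duration_min: float = 10.0,
                  min_fixes: int = 5) -> list[Trip]:
    """Split a speed-filtered deployment into central-place foraging trips.

    A trip is a maximal run of fixes farther than ``colony_radius_km`` from the
    colony, padded with the nearest bounding at-colony fix when one exists so
    that trips start and end at the colony.  Runs shorter than
    ``min_duration_min`` or with fewer than ``min_fixes`` fixes are discarded.
    """
    fx = deployment.fixes.reset_index(drop=True)
    d = haversine_km_vec(fx["lat"], fx["lon"],
                         deployment.colony[0], deployment.colony[1])
    away = np.asarray(d) > colony_radius_km
    if not away.any():
        logger.info("deployment %s never leaves the colony radius", deployment.individual_id)
        return []
    trips: list[Trip] = []
    # maximal runs of consecutive "away" fixes
    edges = np.flatnonzero(np.diff(np.concatenate(([0], away.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        lo = start - 1 if start > 0 else start          # pad with bounding at-colony fix
        hi = stop if stop < len(fx) else stop - 1
        seg = fx.iloc[lo:hi + 1].reset_index(drop=True)
        dur_min = (seg["time"].iloc[-1] - seg["time"].iloc[0]).total_seconds() / 60.0
        if dur_min < min_duration_min or away[start:stop].sum() < min_fixes:
            continue
        trips.append(Trip(deployment.individual_id, deployment.stage,
                          trip_index=len(trips) + 1, fixes=seg))
    return trips


def interpolate_trip(trip: Trip, dt_s: float = 1.0, max_gap_min: float = 30.0) -> Trip:
    """Linearly interpolate trip positions onto an exact ``dt_s`` grid.

    Interpolation is in raw lat/lon; endpoints are preserved (the last fix is
    appended when the span is not a multiple of ``dt_s``).  Gaps longer than
    ``max_gap_min`` are flagged in the log but still interpolated.
    """
    fx = trip.fixes
    if len(fx) < 2:
        raise InvalidInputError("interpolation needs at least two fixes")
    t = fx["time"].to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
    gaps = np.diff(t)
    if (gaps > max_gap_min * 60.0).any():
        logger.warning("trip %s/%d has %d gaps longer than %.0f min (interpolated anyway)",
                       trip.individual_id, trip.trip_index,
                       int((gaps > max_gap_min * 60).sum()), max_gap_min)
    grid = np.arange(t[0], t[-1] + dt_s / 2, dt_s)
    if grid[-1] < t[-1]:
        grid = np.append(grid, t[-1])
    lat = np.interp(grid, t, fx["lat"].to_numpy(float))
    lon = np.interp(grid, t, fx["lon"].to_numpy(float))
    out = pd.DataFrame({
        "time": pd.to_datetime((grid * 1e9).round().astype(np.int64)),
        "lat": lat,
        "lon": lon,
    })
    return replace(trip, fixes=out)


def trip_metrics(trip: Trip, colony: tuple[float, float]) -> Trip:
    """Populate duration, total/maximum distance and heading to the most
    distal point.

    Heading is the initial bearing from the colony to the fix at maximum
    colony distance, in (-180, 180].
    """
    fx = trip.fixes
    t = fx["time"]
    duration_h = (t.iloc[-1] - t.iloc[0]).total_seconds() / 3600.0
    lat = fx["lat"].to_numpy(float)
    lon = fx["lon"].to_numpy(float)
    step = haversine_km_vec(lat[:-1], lon[:-1], lat[1:], lon[1:])
    total = float(np.sum(step))
    dcol = haversine_km_vec(lat, lon, colony[0], colony[1])
    k = int(np.argmax(dcol))
    heading = initial_bearing_deg(colony, (float(lat[k]), float(lon[k])))
    return replace(trip, duration_h=duration_h, total_distance_km=total,
                   max_distance_km=float(dcol[k]), heading_deg=heading)


def project_local_km(lat, lon, colony: tuple[float, float]):
    """Colony-anchored equirectangular projection to (east, north) km offsets."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    x = (lon - colony[1]) * KM_PER_DEG_LON * math.cos(math.radians(colony[0]))
    y = (lat - colony[0]) * KM_PER_DEG_LAT
    return x, y


def unproject_local_km(x, y, colony: tuple[float, float]):
    """Inverse of :func:`project_local_km`: (east, north) km -> (lat, lon)."""
    lat = colony[0] + np.asarray(y, float) / KM_PER_DEG_LAT
    lon = colony[1] + np.asarray(x, float) / (KM_PER_DEG_LON * math.cos(math.radians(colony[0])))
    return lat, lon


def rasterize_trip(trip: Trip, colony: tuple[float, float],
                   cell_km: float = 1.0) -> frozenset[tuple[int, int]]:
    """Grid-cell occupancy of a trip on a colony-anchored square grid.

    The colony sits at a cell corner; cell index is
    ``(floor(x / cell_km), floor(y / cell_km))`` on the local projection.
    """
    if not (cell_km > 0 and math.isfinite(cell_km)):
        raise InvalidInputError(f"cell_km must be positive, got {cell_km}")
    x, y = project_local_km(trip.fixes["lat"], trip.fixes["lon"], colony)
    i = np.floor(x / cell_km).astype(int)
    j = np.floor(y / cell_km).astype(int)
    return frozenset(zip(i.tolist(), j.tolist()))
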