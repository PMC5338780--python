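"""CSV and GeoJSON readers/writers for the pipeline's external formats.

All tables are plain CSV.  Timestamps are ISO-8601 UTC; missing values are
written as ``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dives import DepthSeries
from .errors import SchemaError
from .tracks import Deployment, Trip

GPS_COLUMNS = ["individual_id", "stage", "timestamp", "lat", "lon"]
TDR_COLUMNS = ["individual_id", "timestamp", "depth_m"]
ISO_COLUMNS = ["individual_id", "tissue", "stage", "d13C", "d15N", "cn_ratio"]
DIET_COLUMNS = ["sample_id", "individual_id", "stage", "species", "prey_group", "count"]


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns {missing}")


def read_gps_csv(path, colony: tuple[float, float]) -> list[Deployment]:
    """Read a GPS fix table into one Deployment per individual × stage."""
    df = pd.read_csv(path)
    _require(df, GPS_COLUMNS, "GPS")
    df["time"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    out = []
    for (ind, stage), grp in df.groupby(["individual_id", "stage"], sort=True):
        fixes = grp.sort_values("time")[["time", "lat", "lon"]].reset_index(drop=True)
        out.append(Deployment(individual_id=str(ind), stage=str(stage),
                              colony=colony, fixes=fixes))
    return out


def write_gps_csv(deployments: list[Deployment], path) -> None:
    rows = []
    for dep in deployments:
        for _, fx in dep.fixes.iterrows():
            rows.append({"individual_id": dep.individual_id, "stage": dep.stage,
                         "timestamp": fx["time"].strftime("%Y-%m-%dT%H:%M:%S.%f"),
                         "lat": fx["lat"], "lon": fx["lon"]})
    pd.DataFrame(rows, columns=GPS_COLUMNS).to_csv(path, index=False)


def read_tdr_csv(path) -> list[DepthSeries]:
    df = pd.read_csv(path)
    _require(df, TDR_COLUMNS, "TDR")
    df["time"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    out = []
    for ind, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("time")
        out.append(DepthSeries(individual_id=str(ind),
                               times=grp["time"].reset_index(drop=True),
                               depth_m=grp["depth_m"].to_numpy(float)))
    return out


def write_tdr_csv(depth_frames: dict[str, pd.DataFrame], path) -> None:
    parts = []
    for ind in sorted(depth_frames):
        df = depth_frames[ind]
        parts.append(pd.DataFrame({
            "individual_id": ind,
            "timestamp": df["time"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "depth_m": df["depth_m"],
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_isotope_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ISO_COLUMNS, "isotope")
    return df


def read_diet_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, DIET_COLUMNS, "diet")
    return df


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    """One row per trip with all derived metrics (cells reported as a count)."""
    return pd.DataFrame([{
        "individual_id": tr.individual_id,
        "stage": tr.stage,
        "trip_index": tr.trip_index,
        "start": tr.fixes["time"].iloc[0].strftime("%Y-%m-%dT%H:%M:%S.%f"),
        "end": tr.fixes["time"].iloc[-1].strftime("%Y-%m-%dT%H:%M:%S.%f"),
        "n_fixes": len(tr.fixes),
        "duration_h": tr.duration_h,
        "max_distance_km": tr.max_distance_km,
        "total_distance_km": tr.total_distance_km,
        "heading_deg": tr.heading_deg,
        "n_cells": len(tr.cells),
        "cell_size_km": tr.cell_size_km,
    } for tr in trips])


def write_trips_csv(trips: list[Trip], path) -> None:
    trips_to_frame(trips).to_csv(path, index=False, na_rep="NA")


def write_tracks_geojson(trips: list[Trip], path) -> None:
    """Per-trip LineString export (lon, lat order as GeoJSON requires)."""
    features = []
    for tr in trips:
        coords = [[round(float(lon), 6), round(float(lat), 6)]
                  for lat, lon in zip(tr.fixes["lat"], tr.fixes["lon"])]
        features.append({
            "type": "Feature",
            "properties": {"individual_id": tr.individual_id, "stage": tr.stage,
                           "trip_index": tr.trip_index},
            "geometry": {"type": "LineString", "coordinates": coords},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features},
        separators=(",", ":"), sort_keys=True))
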