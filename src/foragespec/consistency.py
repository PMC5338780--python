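"""Individual-level consistency statistics.

Three ingredients quantify how repeatable an individual's foraging is across
trips within a breeding stage:

* coefficients of variation (CV) of trip metrics — sample SD (n-1) over mean;
* circular mean and circular SD of trip headings, SD = sqrt(-2 ln R̄) with R̄
  the mean resultant length (radians);
* the space-use consistency index: the mean number of grid cells shared by a
  pair of trips, over all unordered pairs, divided by the mean number of
  cells used per trip.  1 means every trip revisits exactly the same cells,
  0 means no two trips share a cell.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .dives import DiveEvent
from .errors import InsufficientDataError, UndefinedStatisticError
from .tracks import Trip, rasterize_trip, wrap_deg

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "individual_id", "stage", "n_trips",
    "mean_duration_h", "mean_max_distance_km", "mean_total_distance_km",
    "mean_heading_deg", "cv_duration", "cv_max_distance", "cv_total_distance",
    "sd_heading", "consistency_index", "mean_max_depth_m", "cv_max_depth",
]


def cv(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    x = np.asarray(list(values), float)
    if len(x) < 2:
        raise InsufficientDataError("CV needs at least two values")
    m = x.mean()
    if m == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(x.std(ddof=1) / m)


def circular_mean_sd(headings_deg) -> tuple[float, float]:
    """Circular mean (degrees, (-180, 180]) and circular SD (radians).

    SD is sqrt(-2 ln R̄); an exactly balanced direction set (R̄ = 0) yields
    +inf.
    """
    h = np.radians(np.asarray(list(headings_deg), float))
    if len(h) == 0:
        raise InsufficientDataError("no headings")
    c, s = np.cos(h).mean(), np.sin(h).mean()
    rbar = math.hypot(c, s)
    mean = wrap_deg(math.degrees(math.atan2(s, c)))
    sd = math.inf if rbar <= 1e-12 else math.sqrt(-2.0 * math.log(min(1.0, rbar)))
    return mean, sd


def space_use_consistency_index(cell_sets, method: str = "ratio_of_means") -> float:
    """Space-use consistency from per-trip grid-cell sets.

    ``ratio_of_means`` (default): mean pairwise shared-cell count over all
    unordered trip pairs, divided by the mean per-trip cell count.
    ``mean_of_ratios``: mean over pairs of |A∩B| / ((|A|+|B|)/2).
    Both lie in [0, 1].
    """
    sets = [frozenset(s) for s in cell_sets]
    if len(sets) < 2:
        raise InsufficientDataError("consistency index needs at least two trips")
    if any(len(s) == 0 for s in sets):
        raise InsufficientDataError("every trip must occupy at least one cell")
    pairs = list(combinations(sets, 2))
    if method == "ratio_of_means":
        mean_shared = np.mean([len(a & b) for a, b in pairs])
        mean_size = np.mean([len(s) for s in sets])
        return float(mean_shared / mean_size)
    if method == "mean_of_ratios":
        return float(np.mean([len(a & b) / ((len(a) + len(b)) / 2.0) for a, b in pairs]))
    raise ValueError(f"unknown method {method!r}")


def index_agreement(index_a, index_b) -> tuple[float, float]:
    """OLS agreement between two per-individual index vectors: (R², slope of b on a)."""
    a = np.asarray(list(index_a), float)
    b = np.asarray(list(index_b), float)
    if len(a) != len(b) or len(a) < 3:
        raise InsufficientDataError("paired values with n >= 3 required")
    if np.allclose(a, a[0]):
        raise UndefinedStatisticError("predictor has zero variance")
    res = stats.linregress(a, b)
    return float(res.rvalue ** 2), float(res.slope)


def build_profiles(trips: list[Trip], dives: list[DiveEvent] | None,
                   colony: tuple[float, float], cell_size_km: float = 1.0,
                   index_method: str = "ratio_of_means") -> pd.DataFrame:
    """One profile row per individual × stage: metric means, CVs, circular
    heading statistics and the space-use consistency index.

    Dive columns are filled only for individuals with dive records.
    Individuals with a single trip get a row with CV/index fields as NaN and
    a logged warning.
    """
    rows = []
    key = lambda tr: (tr.individual_id, tr.stage)
    by_id: dict[tuple[str, str], list[Trip]] = {}
    for tr in trips:
        by_id.setdefault(key(tr), []).append(tr)
    depth_by_ind: dict[str, list[float]] = {}
    for dv in dives or []:
        depth_by_ind.setdefault(dv.individual_id, []).append(dv.max_depth_m)

    for (ind, stage), group in sorted(by_id.items()):
        group = sorted(group, key=lambda tr: tr.trip_index)
        dur = [tr.duration_h for tr in group]
        dmax = [tr.max_distance_km for tr in group]
        dtot = [tr.total_distance_km for tr in group]
        head = [tr.heading_deg for tr in group]
        mean_h, sd_h = circular_mean_sd(head)
        row = {
            "individual_id": ind, "stage": stage, "n_trips": len(group),
            "mean_duration_h": float(np.mean(dur)),
            "mean_max_distance_km": float(np.mean(dmax)),
            "mean_total_distance_km": float(np.mean(dtot)),
            "mean_heading_deg": mean_h,
            "sd_heading": sd_h,
        }
        if len(group) >= 2:
            cells = [tr.cells if tr.cells else rasterize_trip(tr, colony, cell_size_km)
                     for tr in group]
            row.update(
                cv_duration=cv(dur), cv_max_distance=cv(dmax), cv_total_distance=cv(dtot),
                consistency_index=space_use_consistency_index(cells, method=index_method),
            )
        else:
            logger.warning("individual %s/%s has a single trip; CVs and index undefined",
                           ind, stage)
            row.update(cv_duration=np.nan, cv_max_distance=np.nan,
                       cv_total_distance=np.nan, consistency_index=np.nan)
        depths = depth_by_ind.get(ind)
        if depths:
            row["mean_max_depth_m"] = float(np.mean(depths))
            row["cv_max_depth"] = cv(depths) if len(depths) >= 2 else np.nan
        else:
            row["mean_max_depth_m"] = np.nan
            row["cv_max_depth"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
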