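"""Trip-level and step-level movement statistics.

Trip statistics: total path length, mean speed (path length / duration) and
the maximum distance reached from the trip's start/end waterholes (the
nearer of the two at every fix).  Step records carry, for every consecutive
fix pair, the step speed, the progression through the trip (% of total trip
duration elapsed at the step's start) and the distance to the nearest
water-retaining waterhole — the model-ready covariates for the within-trip
speed analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import Trip, _water_xy

#: Trip-duration bin edges (hours): <=12, 12-36, 36-60, 60-84, >84.
DURATION_BIN_EDGES = (0.0, 12.0, 36.0, 60.0, 84.0, np.inf)
DURATION_BIN_LABELS = ("<=12h", "12-36h", "36-60h", "60-84h", ">84h")


@dataclass(frozen=True)
class TripStats:
    trip_id: str
    individual_id: str
    trip_type: str
    duration_h: float
    distance_km: float
    mean_speed_kmh: float
    max_dist_startend_km: float
    short_flag: bool


def _site_xy_km(waterholes: pd.DataFrame, site_id) -> np.ndarray:
    row = waterholes.loc[waterholes["site_id"] == site_id]
    if row.empty:
        raise KeyError(f"unknown waterhole site_id {site_id!r}")
    return row[["x", "y"]].to_numpy(float)[0] / 1000.0


def _dist_startend_km(trip: Trip, waterholes: pd.DataFrame) -> np.ndarray:
    """Per-fix distance (km) to the nearer of the trip's two boundary
    waterholes."""
    fxy = trip.fixes[["x", "y"]].to_numpy(float) / 1000.0
    s = _site_xy_km(waterholes, trip.start_visit.site_id)
    e = _site_xy_km(waterholes, trip.end_visit.site_id)
    ds = np.hypot(fxy[:, 0] - s[0], fxy[:, 1] - s[1])
    de = np.hypot(fxy[:, 0] - e[0], fxy[:, 1] - e[1])
    return np.minimum(ds, de)


def trip_statistics(trip: Trip, waterholes: pd.DataFrame) -> TripStats:
    """Compute one trip's summary statistics (planar km / km/h)."""
    if len(trip.fixes) < 2:
        raise ValueError(f"trip {trip.trip_id} has fewer than 2 fixes")
    xy = trip.fixes[["x", "y"]].to_numpy(float) / 1000.0
    steps = np.hypot(*np.diff(xy, axis=0).T)
    distance_km = float(steps.sum())
    return TripStats(
        trip_id=trip.trip_id,
        individual_id=trip.individual_id,
        trip_type=trip.trip_type,
        duration_h=trip.duration_h,
        distance_km=distance_km,
        mean_speed_kmh=distance_km / trip.duration_h,
        max_dist_startend_km=float(_dist_startend_km(trip, waterholes).max()),
        short_flag=trip.short_flag,
    )


def trip_stats_table(trips: Sequence[Trip], waterholes: pd.DataFrame) -> pd.DataFrame:
    """Model-ready trip-level table (retained trips with >=2 fixes only)."""
    rows = [
        trip_statistics(t, waterholes).__dict__
        for t in trips
        if t.retained and len(t.fixes) >= 2
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df["commuting"] = (df["trip_type"] == "commuting").astype(float)
    return df


def step_records(trip: Trip, waterholes: pd.DataFrame) -> pd.DataFrame:
    """One record per consecutive fix pair of a retained trip.

    speed_kmh = step length / step interval; progression_pct is the % of
    trip duration elapsed at the step's *start* fix (first step: 0, always
    < 100); dist_water_km is the step-start fix's distance to the nearest
    water-retaining waterhole, any site.
    """
    ts = trip.fixes["timestamp"]
    dt_h = ts.diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    if np.any(dt_h <= 0):
        raise ValueError(f"trip {trip.trip_id} has a zero or negative step interval")
    xy = trip.fixes[["x", "y"]].to_numpy(float) / 1000.0
    step_km = np.hypot(*np.diff(xy, axis=0).T)
    elapsed_h = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()[:-1] / 3600.0

    wxy, _ = _water_xy(waterholes)
    start_xy = xy[:-1]
    d_water = np.min(
        np.hypot(start_xy[:, None, 0] - wxy[None, :, 0], start_xy[:, None, 1] - wxy[None, :, 1]),
        axis=1,
    )
    return pd.DataFrame(
        {
            "trip_id": trip.trip_id,
            "individual_id": trip.individual_id,
            "step_index": np.arange(len(step_km)),
            "speed_kmh": step_km / dt_h,
            "progression_pct": 100.0 * elapsed_h / trip.duration_h,
            "dist_water_km": d_water,
            "trip_type": trip.trip_type,
            "duration_h": trip.duration_h,
        }
    )


def step_table(trips: Sequence[Trip], waterholes: pd.DataFrame) -> pd.DataFrame:
    """Concatenated step records over all retained trips."""
    frames = [
        step_records(t, waterholes) for t in trips if t.retained and len(t.fixes) >= 2
    ]
    if not frames:
        return pd.DataFrame()
    df = pd.concat(frames, ignore_index=True)
    df["commuting"] = (df["trip_type"] == "commuting").astype(float)
    return df


@dataclass(frozen=True)
class DurationDistribution:
    """Trip-duration proportions over the five reporting bins, plus a 2-h
    histogram for multimodality inspection."""

    proportions: tuple[float, ...]
    counts: tuple[int, ...]
    histogram_edges_h: tuple[float, ...]
    histogram_counts: tuple[int, ...]

    def as_dict(self) -> dict:
        return {
            "bins": list(DURATION_BIN_LABELS),
            "proportions": list(self.proportions),
            "counts": list(self.counts),
            "histogram_edges_h": list(self.histogram_edges_h),
            "histogram_counts": list(self.histogram_counts),
        }


def duration_distribution(durations_h: Sequence[float]) -> DurationDistribution:
    """Bin trip durations into the five reporting bins (12 h falls in the
    first bin: right-closed intervals)."""
    d = np.asarray(list(durations_h), float)
    if d.size == 0:
        raise ValueError("no trips to bin")
    cut = pd.cut(d, bins=list(DURATION_BIN_EDGES), right=True, include_lowest=True)
    counts = pd.Series(cut).value_counts(sort=False).to_numpy()
    hist_edges = np.arange(0.0, max(96.0, np.ceil(d.max() / 2.0) * 2.0) + 2.0, 2.0)
    hist_counts, _ = np.histogram(d, bins=hist_edges)
    return DurationDistribution(
        proportions=tuple((counts / counts.sum()).tolist()),
        counts=tuple(int(c) for c in counts),
        histogram_edges_h=tuple(hist_edges.tolist()),
        histogram_counts=tuple(int(c) for c in hist_counts),
    )


def apogee_index(trip: Trip, waterholes: pd.DataFrame) -> int:
    """Index of the trip's turning-point fix: the fix attaining the maximum
    distance to the start/end waterholes (earliest on a tie)."""
    return int(np.argmax(_dist_startend_km(trip, waterholes)))


def closest_waterhole_analysis(
    trips: Sequence[Trip],
    waterholes: pd.DataFrame,
    tol_km: float = 0.1,
    reference: str = "apogee",
) -> dict:
    """Did trips end at the waterhole closest to their turning point?

    From each trip's reference point, compare the distance to the waterhole
    actually visited at the trip's end (d_end) with the distance to the
    nearest water-retaining waterhole (d_min).  The trip counts as "not
    closest" when d_end - d_min exceeds ``tol_km`` (a small tolerance
    absorbing GPS error); the extra distance d_end - d_min is averaged over
    those trips.

    reference="apogee" measures from the single turning-point fix;
    reference="return_min" instead takes, for each candidate waterhole, the
    minimum distance over the whole return leg (apogee to end).
    """
    wxy, sites = _water_xy(waterholes)
    extras = []
    not_closest = []
    for trip in trips:
        if not trip.retained or len(trip.fixes) < 2:
            continue
        k = apogee_index(trip, waterholes)
        exy = _site_xy_km(waterholes, trip.end_visit.site_id)
        if reference == "apogee":
            p = trip.fixes[["x", "y"]].to_numpy(float)[k] / 1000.0
            d_end = float(np.hypot(p[0] - exy[0], p[1] - exy[1]))
            d_min = float(np.min(np.hypot(wxy[:, 0] - p[0], wxy[:, 1] - p[1])))
        elif reference == "return_min":
            ret = trip.fixes[["x", "y"]].to_numpy(float)[k:] / 1000.0
            d_end = float(
                np.min(np.hypot(ret[:, 0] - exy[0], ret[:, 1] - exy[1]))
            )
            d_min = float(
                np.min(
                    np.hypot(ret[:, None, 0] - wxy[None, :, 0], ret[:, None, 1] - wxy[None, :, 1])
                )
            )
        else:
            raise ValueError(f"unknown reference {reference!r}")
        extra = d_end - d_min
        flag = extra > tol_km
        not_closest.append(flag)
        if flag:
            extras.append(extra)
    if not not_closest:
        raise ValueError("no retained trips for closest-waterhole analysis")
    extras = np.asarray(extras)
    return {
        "n_trips": len(not_closest),
        "fraction_not_closest": float(np.mean(not_closest)),
        "mean_extra_km": float(extras.mean()) if extras.size else 0.0,
        "sd_extra_km": float(extras.std(ddof=1)) if extras.size > 1 else 0.0,
    }
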