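"""Reading, validation and planar projection of GPS fix and waterhole tables.

Telemetry comes in as geographic coordinates (WGS84 degrees).  All downstream
trip geometry works in a local azimuthal-equidistant frame centered on the
waterhole centroid, so distances are plain Euclidean meters.  Over a study
extent of ~150 km the planar distance between two projected points stays
within 0.5% of the true geodesic, which is far below the GPS error budget.

The projection is built on Vincenty's inverse/direct geodesic formulas for
the WGS84 ellipsoid (vectorized over numpy arrays); distances from the
projection origin are exact geodesics by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)

#: Default column mapping for Movebank-dialect fix CSVs.
MOVEBANK_DIALECT: dict[str, str] = {
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "individual_id": "individual-local-identifier",
}


class GeoIOError(ValueError):
    """Fatal problem with an input table (missing column, empty file...)."""


@dataclass
class Trajectory:
    """Time-ordered GPS fixes of one individual within one sampling window.

    ``fixes`` holds columns ``timestamp`` (tz-aware UTC), ``lon``, ``lat``
    and, after :func:`project`, planar ``x``/``y`` in meters.
    """

    individual_id: str
    fixes: pd.DataFrame
    window: str = "all"

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("trajectory timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(float)


@dataclass
class ReadReport:
    """Row-level accounting from a fix-table read."""

    n_rows: int = 0
    n_kept: int = 0
    n_bad_timestamp: int = 0
    n_bad_coords: int = 0
    n_duplicate_timestamp: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def read_fixes(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    windows: Sequence[tuple[str, pd.Timestamp, pd.Timestamp]] | None = None,
) -> tuple[list[Trajectory], ReadReport]:
    """Read a fix CSV into one :class:`Trajectory` per (individual, window).

    Rows with unparseable timestamps or out-of-range coordinates are dropped
    and counted in the returned :class:`ReadReport`.  Duplicate timestamps
    within an individual keep the first occurrence.  ``windows`` optionally
    assigns fixes to labelled sampling windows ``(label, start, end]``;
    without it every fix falls in a single window ``"all"``.
    """
    dialect = dict(MOVEBANK_DIALECT, **(dialect or {}))
    path = Path(path)
    if not path.exists():
        raise GeoIOError(f"fix file not found: {path}")
    raw = pd.read_csv(path, dtype={dialect["individual_id"]: str})
    if raw.empty:
        raise GeoIOError(f"fix file is empty: {path}")
    missing = [c for c in dialect.values() if c not in raw.columns]
    if missing:
        raise GeoIOError(f"fix file {path} is missing required column(s): {missing}")

    df = pd.DataFrame(
        {
            "individual_id": raw[dialect["individual_id"]].astype(str),
            "timestamp": pd.to_datetime(raw[dialect["timestamp"]], utc=True, errors="coerce"),
            "lon": pd.to_numeric(raw[dialect["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[dialect["lat"]], errors="coerce"),
        }
    )
    report = ReadReport(n_rows=len(df))

    bad_ts = df["timestamp"].isna()
    report.n_bad_timestamp = int(bad_ts.sum())
    df = df[~bad_ts]

    bad_xy = (
        df["lon"].isna()
        | df["lat"].isna()
        | (df["lon"].abs() > 180.0)
        | (df["lat"].abs() > 90.0)
    )
    report.n_bad_coords = int(bad_xy.sum())
    df = df[~bad_xy]

    df = df.sort_values(["individual_id", "timestamp"], kind="stable")
    dup = df.duplicated(subset=["individual_id", "timestamp"], keep="first")
    report.n_duplicate_timestamp = int(dup.sum())
    df = df[~dup]
    report.n_kept = len(df)

    trajectories: list[Trajectory] = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.reset_index(drop=True)
        if windows is None:
            trajectories.append(Trajectory(str(ind), sub.drop(columns="individual_id")))
            continue
        for label, start, end in windows:
            mask = (sub["timestamp"] > pd.Timestamp(start)) & (
                sub["timestamp"] <= pd.Timestamp(end)
            )
            if mask.any():
                trajectories.append(
                    Trajectory(
                        str(ind),
                        sub[mask].reset_index(drop=True).drop(columns="individual_id"),
                        window=str(label),
                    )
                )
    return trajectories, report


def write_fixes(
    trajectories: Iterable[Trajectory],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write trajectories back to a fix CSV in the given dialect (lossless
    for the mapped columns)."""
    dialect = dict(MOVEBANK_DIALECT, **(dialect or {}))
    frames = []
    for traj in trajectories:
        out = pd.DataFrame(
            {
                dialect["timestamp"]: traj.fixes["timestamp"].dt.strftime(
                    "%Y-%m-%d %H:%M:%S"
                ),
                dialect["lon"]: traj.fixes["lon"],
                dialect["lat"]: traj.fixes["lat"],
                dialect["individual_id"]: traj.individual_id,
            }
        )
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_waterholes(path: str | Path) -> pd.DataFrame:
    """Read a waterhole table (site_id, lon, lat, has_water)."""
    path = Path(path)
    if not path.exists():
        raise GeoIOError(f"waterhole file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ("site_id", "lon", "lat", "has_water") if c not in df.columns]
    if missing:
        raise GeoIOError(f"waterhole file {path} is missing column(s): {missing}")
    if df.empty:
        raise GeoIOError(f"waterhole file is empty: {path}")
    if df["site_id"].duplicated().any():
        raise GeoIOError("waterhole site_id values must be unique")
    df = df.copy()
    df["has_water"] = df["has_water"].astype(int).astype(bool)
    return df


# ---------------------------------------------------------------------------
# Vincenty geodesics (vectorized, WGS84)
# ---------------------------------------------------------------------------

def _vincenty_inverse(
    lat1: float, lon1: float, lat2: np.ndarray, lon2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Geodesic distance (m) and forward azimuth (rad) from a single origin
    to arrays of points."""
    lat2 = np.atleast_1d(np.asarray(lat2, float))
    lon2 = np.atleast_1d(np.asarray(lon2, float))
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - _WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1 - _WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    for _ in range(200):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(sin_sigma > 0, cosU1 * cosU2 * sin_lam / sin_sigma, 0.0)
        cos2_alpha = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            cos_2sm = np.where(
                cos2_alpha > 0, cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha, 0.0
            )
        C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_new = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm**2))
        )
        if np.all(np.abs(lam_new - lam) < 1e-13):
            lam = lam_new
            break
        lam = lam_new

    sin_lam, cos_lam = np.sin(lam), np.cos(lam)
    sin_sigma = np.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
    sigma = np.arctan2(sin_sigma, cos_sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_alpha = np.where(sin_sigma > 0, cosU1 * cosU2 * sin_lam / sin_sigma, 0.0)
    cos2_alpha = 1.0 - sin_alpha**2
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_2sm = np.where(
            cos2_alpha > 0, cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha, 0.0
        )
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sm
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sm**2)
                - B
                / 6
                * cos_2sm
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sm**2)
            )
        )
    )
    s = _WGS84_B * A * (sigma - delta_sigma)
    alpha1 = np.arctan2(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    return s, alpha1


def _vincenty_direct(
    lat1: float, lon1: float, alpha1: np.ndarray, s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Destination (lat, lon in degrees) from a single origin given forward
    azimuth (rad) and geodesic distance (m)."""
    alpha1 = np.atleast_1d(np.asarray(alpha1, float))
    s = np.atleast_1d(np.asarray(s, float))
    phi1 = np.radians(lat1)
    U1 = np.arctan((1 - _WGS84_F) * np.tan(phi1))
    sigma1 = np.arctan2(np.tan(U1), np.cos(alpha1))
    sin_alpha = np.cos(U1) * np.sin(alpha1)
    cos2_alpha = 1.0 - sin_alpha**2
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))

    sigma = s / (_WGS84_B * A)
    for _ in range(200):
        cos_2sm = np.cos(2 * sigma1 + sigma)
        sin_sigma, cos_sigma = np.sin(sigma), np.cos(sigma)
        delta_sigma = (
            B
            * sin_sigma
            * (
                cos_2sm
                + B
                / 4
                * (
                    cos_sigma * (-1 + 2 * cos_2sm**2)
                    - B
                    / 6
                    * cos_2sm
                    * (-3 + 4 * sin_sigma**2)
                    * (-3 + 4 * cos_2sm**2)
                )
            )
        )
        sigma_new = s / (_WGS84_B * A) + delta_sigma
        if np.all(np.abs(sigma_new - sigma) < 1e-13):
            sigma = sigma_new
            break
        sigma = sigma_new

    sin_sigma, cos_sigma = np.sin(sigma), np.cos(sigma)
    cos_2sm = np.cos(2 * sigma1 + sigma)
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    cos_alpha1, sin_alpha1 = np.cos(alpha1), np.sin(alpha1)
    phi2 = np.arctan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * cos_alpha1,
        (1 - _WGS84_F)
        * np.hypot(sin_alpha, sinU1 * sin_sigma - cosU1 * cos_sigma * cos_alpha1),
    )
    lam = np.arctan2(
        sin_sigma * sin_alpha1, cosU1 * cos_sigma - sinU1 * sin_sigma * cos_alpha1
    )
    C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
    L = lam - (1 - C) * _WGS84_F * sin_alpha * (
        sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm**2))
    )
    return np.degrees(phi2), lon1 + np.degrees(L)


@dataclass(frozen=True)
class LocalProjection:
    """Azimuthal-equidistant projection centered on (lon0, lat0).

    ``forward`` maps degrees to meters east/north of the origin; distances
    from the origin equal the WGS84 geodesic by construction.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.atleast_1d(np.asarray(lon, float))
        lat = np.atleast_1d(np.asarray(lat, float))
        s, az = _vincenty_inverse(self.lat0, self.lon0, lat, lon)
        at_origin = s < 1e-9
        x = np.where(at_origin, 0.0, s * np.sin(az))
        y = np.where(at_origin, 0.0, s * np.cos(az))
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        s = np.hypot(x, y)
        az = np.arctan2(x, y)
        lat, lon = _vincenty_direct(self.lat0, self.lon0, az, s)
        lat = np.where(s < 1e-9, self.lat0, lat)
        lon = np.where(s < 1e-9, self.lon0, lon)
        return lon, lat


def project(
    trajectories: Sequence[Trajectory],
    waterholes: pd.DataFrame,
    origin: tuple[float, float] | str = "auto",
) -> LocalProjection:
    """Fill planar ``x``/``y`` (meters) on trajectories and waterholes.

    ``origin="auto"`` centers the frame on the waterhole centroid.  Mutates
    the inputs in place and returns the projection used.
    """
    if origin == "auto":
        lon0 = float(waterholes["lon"].mean())
        lat0 = float(waterholes["lat"].mean())
    else:
        lon0, lat0 = float(origin[0]), float(origin[1])

    lons = [waterholes["lon"].to_numpy()] + [t.fixes["lon"].to_numpy() for t in trajectories]
    lats = [waterholes["lat"].to_numpy()] + [t.fixes["lat"].to_numpy() for t in trajectories]
    all_lon = np.concatenate(lons)
    all_lat = np.concatenate(lats)
    if all_lon.size and (
        lon0 < all_lon.min() - 5
        or lon0 > all_lon.max() + 5
        or lat0 < all_lat.min() - 5
        or lat0 > all_lat.max() + 5
    ):
        warnings.warn(
            "projection origin lies >5 degrees outside the data bounding box",
            stacklevel=2,
        )

    proj = LocalProjection(lon0=lon0, lat0=lat0)
    wx, wy = proj.forward(waterholes["lon"].to_numpy(), waterholes["lat"].to_numpy())
    waterholes["x"], waterholes["y"] = wx, wy
    for traj in trajectories:
        x, y = proj.forward(traj.fixes["lon"].to_numpy(), traj.fixes["lat"].to_numpy())
        traj.fixes["x"], traj.fixes["y"] = x, y
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise GeoIOError(f"non-finite projected coordinates for {traj.individual_id}")
    return proj


def distance(a, b) -> float | np.ndarray:
    """Euclidean distance in meters between planar points (x, y)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return np.hypot(*(a - b).T) if a.ndim > 1 else float(np.hypot(a[0] - b[0], a[1] - b[1]))
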