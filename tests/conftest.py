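"""Shared fixtures: hand-built planar trajectories and seeded synthetic
datasets loaded through the normal I/O path."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from watertrips import geo, simulate

BASE_TIME = pd.Timestamp("2009-09-15T00:00:00Z")


def planar_traj(
    xy_km, hours=None, individual: str = "e1", window: str = "all"
) -> geo.Trajectory:
    """Build a Trajectory directly in the planar frame (km in, meters
    stored), bypassing lon/lat projection."""
    xy = np.asarray(xy_km, float)
    if hours is None:
        hours = np.arange(len(xy), dtype=float)
    fixes = pd.DataFrame(
        {
            "timestamp": BASE_TIME + pd.to_timedelta(np.asarray(hours, float), unit="h"),
            "lon": 0.0,
            "lat": 0.0,
            "x": xy[:, 0] * 1000.0,
            "y": xy[:, 1] * 1000.0,
        }
    )
    return geo.Trajectory(individual, fixes, window=window)


def planar_waterholes(xy_km, has_water=None) -> pd.DataFrame:
    xy = np.atleast_2d(np.asarray(xy_km, float))
    if has_water is None:
        has_water = [True] * len(xy)
    return pd.DataFrame(
        {
            "site_id": [f"W{i:02d}" for i in range(len(xy))],
            "lon": 0.0,
            "lat": 0.0,
            "x": xy[:, 0] * 1000.0,
            "y": xy[:, 1] * 1000.0,
            "has_water": list(has_water),
        }
    )


def load_dataset(
    ds: simulate.SynthDataset, tmpdir, origin="auto"
) -> tuple[list, pd.DataFrame]:
    """Round a generated dataset through CSV + projection, as the pipeline
    does."""
    paths = ds.write(tmpdir)
    trajectories, _ = geo.read_fixes(paths["fixes"])
    waterholes = geo.read_waterholes(paths["waterholes"])
    geo.project(trajectories, waterholes, origin=origin)
    return trajectories, waterholes


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Noise-free, gap-free conditions: segmentation should recover the
    generator's trips exactly."""
    cfg = simulate.noise_free(simulate.SynthConfig(seed=5, n_individuals=5, window_h=250))
    ds = simulate.generate_dataset(cfg)
    # project at the generator origin so true positions survive the
    # round-trip without cross-projection distortion
    trajs, wh = load_dataset(ds, tmp_path_factory.mktemp("clean"), origin=cfg.origin_lonlat)
    return ds, trajs, wh


@pytest.fixture(scope="session")
def noisy_dataset(tmp_path_factory):
    """Default study conditions (GPS error, acquisition gaps)."""
    cfg = simulate.SynthConfig(seed=11, n_individuals=8, window_h=336)
    ds = simulate.generate_dataset(cfg)
    trajs, wh = load_dataset(ds, tmp_path_factory.mktemp("noisy"))
    return ds, trajs, wh
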