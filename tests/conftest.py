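"""Shared fixtures and independent Monte-Carlo oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from sptkinetics import AcquisitionSettings, Localization, Trajectory, TrajectoryDataset

hyp_settings.register_profile("ci", derandomize=True, max_examples=25,
                              deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture
def fast_settings() -> AcquisitionSettings:
    return AcquisitionSettings(frame_interval_s=0.007477, exposure_s=0.001,
                               localization_error_um=0.045,
                               detection_depth_um=0.7, gaps_allowed=1,
                               jumps_considered=4, d_max_um2s=20.0)


@pytest.fixture
def slow_settings() -> AcquisitionSettings:
    return AcquisitionSettings(frame_interval_s=0.5, exposure_s=0.5,
                               localization_error_um=0.03,
                               detection_depth_um=0.7, gaps_allowed=1)


def make_track(track_id: str, frames, xs, ys, dt: float) -> Trajectory:
    locs = tuple(Localization(track_id, int(f), f * dt, float(x), float(y))
                 for f, x, y in zip(frames, xs, ys))
    return Trajectory(track_id, locs)


def make_dataset(settings: AcquisitionSettings, tracks, metadata=None) -> TrajectoryDataset:
    return TrajectoryDataset(settings, tuple(tracks), dict(metadata or {}))


def mc_slab_survival(d_um2s: float, frame_interval_s: float, dz_um: float,
                     n_lags: int, gaps_allowed: int, n_walkers: int = 100_000,
                     seed: int = 0) -> np.ndarray:
    """Monte-Carlo slab oracle, independent of the grid-propagation code:
    walkers start uniform in the slab, take Gaussian axial steps, are
    checked against |z| <= dz/2 at frame times, may re-enter within
    ``gaps_allowed`` consecutive missed frames, and are lost otherwise.
    Returns detection survival at lags 1..n_lags."""
    rng = np.random.default_rng(seed)
    h = dz_um / 2.0
    z = rng.uniform(-h, h, n_walkers)
    miss = np.zeros(n_walkers, dtype=np.int64)
    alive = np.ones(n_walkers, dtype=bool)
    out = np.empty(n_lags)
    step_sd = np.sqrt(2.0 * d_um2s * frame_interval_s)
    for i in range(n_lags):
        z = z + rng.standard_normal(n_walkers) * step_sd
        inside = np.abs(z) <= h
        miss = np.where(inside, 0, miss + 1)
        alive &= miss <= gaps_allowed
        out[i] = (alive & inside).mean()
    return out
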