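"""Shared fixtures: noise-free ideal maps and small simulated sessions."""

import numpy as np
import pytest

import gridframe as gf
from gridframe.ratemap import RateMap

PLATFORM_EXTENT = (-69.0, 69.0, -69.0, 69.0)


def make_ideal_map(scale=60.0, orientation=0.0, phase=(0.0, 0.0),
                   peak=15.0, extent=PLATFORM_EXTENT, bin_size=3.0,
                   **truth_kwargs) -> RateMap:
    """Noise-free rate map: the grid rate function sampled at bin centers."""
    truth = gf.GridGroundTruth(scale=scale, orientation=orientation,
                               phase=phase, peak_rate=peak, **truth_kwargs)
    x0, x1, y0, y1 = extent
    nx = int(round((x1 - x0) / bin_size))
    ny = int(round((y1 - y0) / bin_size))
    x_edges = x0 + np.arange(nx + 1) * bin_size
    y_edges = y0 + np.arange(ny + 1) * bin_size
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    X, Y = np.meshgrid(xc, yc)
    rate = gf.grid_rate_function(np.column_stack([X.ravel(), Y.ravel()]),
                                 truth).reshape(ny, nx)
    return RateMap(rate, x_edges, y_edges, bin_size=bin_size, frame="room")


def map_from_array(arr, bin_size=3.0) -> RateMap:
    arr = np.asarray(arr, dtype=float)
    ny, nx = arr.shape
    x_edges = -bin_size * nx / 2 + np.arange(nx + 1) * bin_size
    y_edges = -bin_size * ny / 2 + np.arange(ny + 1) * bin_size
    return RateMap(arr, x_edges, y_edges, bin_size=bin_size)


@pytest.fixture(scope="session")
def ideal_map_60():
    return make_ideal_map(scale=60.0, orientation=0.0, phase=(0.0, 0.0))


@pytest.fixture(scope="session")
def ideal_map_60_o7():
    return make_ideal_map(scale=60.0, orientation=7.0, phase=(5.0, 3.0))


@pytest.fixture(scope="session")
def short_grid_session():
    """A 600-s simulated session of one ideal grid cell (scale 60, 7 deg)."""
    traj = gf.simulate_trajectory(600.0, seed=101)
    truth = gf.GridGroundTruth(scale=60.0, orientation=7.0, phase=(5.0, 3.0))
    spikes = gf.generate_spikes(
        traj, lambda p: gf.grid_rate_function(p, truth), truth.peak_rate,
        seed=102,
    )
    return traj, spikes, truth


@pytest.fixture(scope="session")
def short_grid_map(short_grid_session):
    traj, spikes, _ = short_grid_session
    return gf.session_rate_map(traj, spikes, extent=PLATFORM_EXTENT)
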