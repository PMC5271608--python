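"""Rate-map pipeline: speed estimation, immobility filtering, binning,
renormalized smoothing, bootstrap resampling, split-half stability."""

import numpy as np
import pytest

import gridframe as gf
from gridframe.io import SpikeTrain, Trajectory
from gridframe.ratemap import (
    InsufficientDataError,
    bootstrap_rate_maps,
    compute_rate_map,
    estimate_speed,
    filter_immobility,
    pearson_overlap,
    rotate_rate_map,
    session_rate_map,
    smooth_rate_map,
    split_half_correlation,
    translate_rate_map,
)
from conftest import PLATFORM_EXTENT, map_from_array

FR = 30.0
DT = 1.0 / FR


def _traj_from_xy(x, y):
    t = np.arange(len(x)) * DT
    return Trajectory(t, x, y, frame_rate=FR)


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------

def test_speed_zero_when_stationary():
    traj = _traj_from_xy(np.full(100, 3.0), np.full(100, -2.0))
    np.testing.assert_allclose(estimate_speed(traj), 0.0, atol=1e-12)


def test_speed_constant_on_straight_line():
    n = 200
    x = 10.0 * np.arange(n) * DT  # 10 cm/s along x
    traj = _traj_from_xy(x, np.zeros(n))
    speed = estimate_speed(traj)
    hw = 18  # clipped mask half-width at 30 Hz (2 sigma of 300 ms)
    np.testing.assert_allclose(speed[hw + 1 : n - hw], 10.0, atol=1e-9)


def test_speed_matches_direct_convolution_oracle():
    rng = np.random.default_rng(3)
    n = 120
    x = np.cumsum(rng.normal(0, 0.5, n))
    y = np.cumsum(rng.normal(0, 0.5, n))
    traj = _traj_from_xy(x, y)
    sigma_frames = 0.3 * FR
    hw = int(round(2 * sigma_frames))
    w = np.exp(-np.arange(-hw, hw + 1) ** 2 / (2 * sigma_frames**2))
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):  # explicit renormalized weighted sum
        lo, hi = max(0, i - hw), min(n, i + hw + 1)
        ww = w[lo - i + hw : hi - i + hw]
        xs[i] = (x[lo:hi] * ww).sum() / ww.sum()
        ys[i] = (y[lo:hi] * ww).sum() / ww.sum()
    expected = np.hypot(np.diff(xs), np.diff(ys)) * FR
    speed = estimate_speed(traj)
    np.testing.assert_allclose(speed[1:], expected, atol=1e-9)
    with pytest.raises(ValueError):
        estimate_speed(_traj_from_xy([0.0], [0.0]))


# ---------------------------------------------------------------------------
# immobility filter
# ---------------------------------------------------------------------------

def _piecewise_speed_traj(slow_steps):
    """Fast run, a slow stretch of ``slow_steps`` frames, fast run."""
    steps = [1.0] * 60 + [0.02] * slow_steps + [1.0] * 60  # cm per frame
    x = np.concatenate([[0.0], np.cumsum(steps)])
    return _traj_from_xy(x, np.zeros_like(x))


@pytest.mark.parametrize("slow_steps,removed", [(18, True), (12, False)])
def test_immobility_epoch_boundary(slow_steps, removed):
    """Epochs strictly longer than 500 ms are expunged; shorter are kept."""
    traj = _piecewise_speed_traj(slow_steps)
    slow_t = traj.t[61 : 61 + slow_steps]
    spikes = SpikeTrain((1, 1, 1, 1), slow_t[: 3])
    # near-zero temporal smoothing isolates the epoch-boundary rule
    ftraj, fspikes = filter_immobility(traj, spikes, temporal_sigma=1e-3)
    if removed:
        assert len(ftraj) == len(traj) - slow_steps
        assert len(fspikes) == 0
    else:
        assert len(ftraj) == len(traj)
        assert len(fspikes) == 3


def test_all_fast_unchanged():
    traj = _piecewise_speed_traj(0)
    spikes = SpikeTrain((1, 1, 1, 1), [0.5, 1.0])
    ftraj, fspikes = filter_immobility(traj, spikes, temporal_sigma=1e-3)
    assert len(ftraj) == len(traj)
    assert len(fspikes) == 2


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_zero_spikes_give_zero_rates():
    traj = gf.simulate_trajectory(120.0, seed=2)
    rm = compute_rate_map(traj, SpikeTrain((1, 1, 1, 1), []),
                          extent=PLATFORM_EXTENT)
    assert np.all(rm.rate[rm.valid] == 0.0)
    with pytest.raises(ValueError):
        compute_rate_map(Trajectory([], [], []), SpikeTrain((1, 1, 1, 1), []))


def test_low_dwell_bin_is_missing():
    # one frame (33 ms) in an isolated bin -> below the 50 ms minimum
    x = np.concatenate([np.zeros(30), [30.0], np.zeros(30)])
    traj = _traj_from_xy(x, np.zeros_like(x))
    rm = compute_rate_map(traj, SpikeTrain((1, 1, 1, 1), []),
                          extent=(-33, 33, -33, 33))
    iy = np.searchsorted(rm.y_edges, 0.0, side="right") - 1
    ix = np.searchsorted(rm.x_edges, 30.0, side="right") - 1
    assert not np.isfinite(rm.rate[iy, ix])
    ix0 = np.searchsorted(rm.x_edges, 0.0, side="right") - 1
    assert np.isfinite(rm.rate[iy, ix0])


def test_spike_count_conservation():
    traj = gf.simulate_trajectory(300.0, seed=3)
    truth = gf.GridGroundTruth(scale=60.0)
    spikes = gf.generate_spikes(
        traj, lambda p: gf.grid_rate_function(p, truth), truth.peak_rate,
        seed=4,
    )
    ftraj, fspikes = filter_immobility(traj, spikes)
    rm = compute_rate_map(ftraj, fspikes, extent=PLATFORM_EXTENT)
    assert rm.spike_count.sum() == len(fspikes)


def test_homogeneous_rate_recovered():
    traj = gf.simulate_trajectory(600.0, seed=5)
    r = 10.0
    spikes = gf.generate_spikes(
        traj, lambda p: np.full(np.atleast_2d(p).shape[0], r), r, seed=6
    )
    rm = session_rate_map(traj, spikes, extent=PLATFORM_EXTENT)
    vals = rm.rate[rm.valid]
    se = vals.std() / np.sqrt(len(vals))
    assert abs(vals.mean() - r) < max(3 * se, 0.05 * r)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_oracle(rate, size=5, variance=2.0, min_occupied=5):
    """Explicit double-loop renormalized Gaussian smoothing."""
    ny, nx = rate.shape
    hw = size // 2
    out = np.full_like(rate, np.nan)
    for i in range(ny):
        for j in range(nx):
            num = den = 0.0
            cnt = 0
            for di in range(-hw, hw + 1):
                for dj in range(-hw, hw + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx and np.isfinite(rate[ii, jj]):
                        w = np.exp(-(di**2 + dj**2) / (2 * variance))
                        num += w * rate[ii, jj]
                        den += w
                        cnt += 1
            if cnt >= min_occupied:
                out[i, j] = num / den
    return out


def test_smoothing_matches_double_loop_oracle():
    rng = np.random.default_rng(7)
    rate = rng.uniform(0, 10, (20, 20))
    rate[rng.random((20, 20)) < 0.3] = np.nan
    rm = map_from_array(rate)
    got = smooth_rate_map(rm).rate
    want = smooth_oracle(rate)
    np.testing.assert_allclose(got, want, atol=1e-9, equal_nan=True)


def test_smoothing_preserves_constants_and_is_convex():
    rm = map_from_array(np.full((15, 15), 4.2))
    np.testing.assert_allclose(smooth_rate_map(rm).rate, 4.2, atol=1e-12)
    rng = np.random.default_rng(8)
    rate = rng.uniform(0, 10, (15, 15))
    sm = smooth_rate_map(map_from_array(rate)).rate
    assert np.nanmin(sm) >= rate.min() - 1e-12
    assert np.nanmax(sm) <= rate.max() + 1e-12


def test_sparse_neighborhood_marked_missing():
    rate = np.full((12, 12), np.nan)
    rate[5, 5:9] = 1.0  # only 4 occupied bins anywhere
    sm = smooth_rate_map(map_from_array(rate)).rate
    assert np.all(~np.isfinite(sm))
    rate[6, 5] = 1.0  # fifth occupied bin
    sm = smooth_rate_map(map_from_array(rate)).rate
    assert np.isfinite(sm[5, 6])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_and_counts(short_grid_session):
    traj, spikes, _ = short_grid_session
    a = bootstrap_rate_maps(traj, spikes, n=3, seed=11, extent=PLATFORM_EXTENT)
    b = bootstrap_rate_maps(traj, spikes, n=3, seed=11, extent=PLATFORM_EXTENT)
    for ma, mb in zip(a, b):
        np.testing.assert_array_equal(ma.rate, mb.rate)
    with pytest.raises(ValueError):
        bootstrap_rate_maps(traj, SpikeTrain((1, 1, 1, 1), []), n=2, seed=1)


def test_bootstrap_single_spike_equals_pipeline():
    # with one spike, resampling with replacement is the identity
    traj = gf.simulate_trajectory(120.0, seed=12)
    spikes = SpikeTrain((1, 1, 1, 1), [40.0])
    boot = bootstrap_rate_maps(traj, spikes, n=1, seed=0,
                               extent=PLATFORM_EXTENT)[0]
    direct = session_rate_map(traj, spikes, extent=PLATFORM_EXTENT)
    np.testing.assert_allclose(boot.rate, direct.rate, atol=1e-12,
                               equal_nan=True)


def test_bootstrap_mean_converges_to_original(short_grid_session):
    traj, spikes, _ = short_grid_session
    original = session_rate_map(traj, spikes, extent=PLATFORM_EXTENT)

    def mad(n, seed):
        maps = bootstrap_rate_maps(traj, spikes, n=n, seed=seed,
                                   extent=PLATFORM_EXTENT)
        mean = np.nanmean(np.stack([m.rate for m in maps]), axis=0)
        d = np.abs(mean - original.rate)
        return np.nanmean(d[original.valid])

    assert mad(200, 13) < mad(10, 13)


# ---------------------------------------------------------------------------
# split-half stability
# ---------------------------------------------------------------------------

def test_split_half_identical_halves():
    base = gf.simulate_trajectory(960.0, seed=14)
    t2 = np.concatenate([base.t, base.t + base.t[-1] + DT])
    traj = Trajectory(t2, np.tile(base.x, 2), np.tile(base.y, 2),
                      frame_rate=FR)
    truth = gf.GridGroundTruth(scale=60.0)
    st = gf.generate_spikes(base, lambda p: gf.grid_rate_function(p, truth),
                            truth.peak_rate, seed=15)
    times = np.concatenate([st.spike_times, st.spike_times + base.t[-1] + DT])
    r = split_half_correlation(traj, SpikeTrain((1, 1, 1, 1), times),
                               extent=PLATFORM_EXTENT)
    assert r > 0.99


def test_split_half_requires_long_session():
    traj = gf.simulate_trajectory(600.0, seed=16)
    with pytest.raises(InsufficientDataError):
        split_half_correlation(traj, SpikeTrain((1, 1, 1, 1), [10.0]))


def test_split_half_stable_grid_and_noise():
    traj = gf.simulate_trajectory(2400.0, seed=17)  # 40 min
    truth = gf.GridGroundTruth(scale=60.0, orientation=7.0)
    grid_spk = gf.generate_spikes(
        traj, lambda p: gf.grid_rate_function(p, truth), truth.peak_rate,
        seed=18,
    )
    r_grid = split_half_correlation(traj, grid_spk, extent=PLATFORM_EXTENT)
    assert r_grid > 0.6
    flat = gf.generate_spikes(
        traj, lambda p: np.full(np.atleast_2d(p).shape[0], 3.0), 3.0, seed=19
    )
    r_flat = split_half_correlation(traj, flat, extent=PLATFORM_EXTENT)
    assert abs(r_flat) < 0.2


# ---------------------------------------------------------------------------
# geometric resampling
# ---------------------------------------------------------------------------

def test_rotate_map_quarter_turn_moves_bump():
    rate = np.zeros((21, 21))
    rate[10, 15] = 5.0  # bump at +x
    rm = map_from_array(rate, bin_size=3.0)
    rot = rotate_rate_map(rm, 90.0)  # CW: +x -> -y
    iy, ix = np.unravel_index(np.nanargmax(rot.rate), rot.rate.shape)
    assert (iy, ix) == (5, 10)


def test_translate_map_shifts_content():
    rate = np.zeros((21, 21))
    rate[10, 10] = 5.0
    rm = map_from_array(rate, bin_size=3.0)
    out = translate_rate_map(rm, 6.0, -3.0)
    iy, ix = np.unravel_index(np.nanargmax(out.rate), out.rate.shape)
    assert (iy, ix) == (9, 12)


def test_rotation_roundtrip_preserves_pattern(ideal_map_60_o7):
    back = rotate_rate_map(rotate_rate_map(ideal_map_60_o7, 33.0), -33.0)
    r = pearson_overlap(back, ideal_map_60_o7)
    assert r > 0.999
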