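"""Synthetic-session generator: determinism, lattice model, Poisson spikes,
manipulation algebra, occupancy statistics."""

import numpy as np
import pytest

import gridframe as gf
from gridframe.ratemap import compute_rate_map, filter_immobility
from gridframe.synthetic import (
    GridGroundTruth,
    UnitSpec,
    apply_manipulation,
    boundary_rate_function,
    generate_spikes,
    grid_rate_function,
    make_session,
    simulate_trajectory,
)


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def test_trajectory_determinism_and_bounds():
    a = simulate_trajectory(60.0, seed=4)
    b = simulate_trajectory(60.0, seed=4)
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.y, b.y)
    half = 137.0 / 2.0
    assert np.all(np.abs(a.x) <= half) and np.all(np.abs(a.y) <= half)
    assert len(a) == 1800
    assert simulate_trajectory(0.0, seed=1).t.size == 0
    with pytest.raises(ValueError):
        simulate_trajectory(-1.0, seed=1)


def test_trajectory_contains_pause_epochs():
    traj = simulate_trajectory(600.0, seed=5)
    speed = gf.estimate_speed(traj)
    slow = speed < 3.0
    # longest slow run exceeds the 500 ms immobility definition
    runs = np.diff(np.flatnonzero(np.diff(np.r_[0, slow.view(np.int8), 0])))
    longest = max(runs[::2], default=0)
    assert longest / traj.frame_rate > 0.5


def test_occupancy_uniformity_after_twenty_minutes():
    """Long foraging covers nearly every bin with near-uniform dwell."""
    traj = simulate_trajectory(1200.0, seed=6)
    ftraj, _ = filter_immobility(traj)
    rm = compute_rate_map(ftraj, gf.SpikeTrain((1, 1, 1, 1), []),
                          extent=(-69, 69, -69, 69))
    occ = rm.occupancy
    X, Y = np.meshgrid(rm.x_centers, rm.y_centers)
    on_platform = (np.abs(X) <= 68.5) & (np.abs(Y) <= 68.5)
    assert (occ[on_platform] >= 0.05).mean() >= 0.95
    interior = (np.abs(X) <= 67.0) & (np.abs(Y) <= 67.0)  # whole bins only
    cv = occ[interior].std() / occ[interior].mean()
    assert cv < 0.5


# ---------------------------------------------------------------------------
# grid and boundary rate functions
# ---------------------------------------------------------------------------

def test_grid_rate_peak_at_vertices_and_periodicity():
    truth = GridGroundTruth(scale=60.0, orientation=17.0, phase=(4.0, -9.0),
                            peak_rate=15.0)
    assert grid_rate_function(np.array(truth.phase), truth) == pytest.approx(15.0)
    th = np.radians(truth.orientation)
    a1 = 60.0 * np.array([np.cos(th), np.sin(th)])
    a2 = 60.0 * np.array([np.cos(th + np.pi / 3), np.sin(th + np.pi / 3)])
    rng = np.random.default_rng(0)
    pts = rng.uniform(-100, 100, size=(50, 2))
    for vec in (a1, a2, 3 * a1 - 2 * a2):
        np.testing.assert_allclose(
            grid_rate_function(pts + vec, truth),
            grid_rate_function(pts, truth), atol=1e-9,
        )
    with pytest.raises(ValueError):
        GridGroundTruth(scale=-1.0)


def test_grid_rate_bump_model_matches_peak():
    truth = GridGroundTruth(scale=50.0, model="bumps")
    assert grid_rate_function(np.array([0.0, 0.0]), truth) == pytest.approx(
        truth.peak_rate
    )


def test_boundary_rate_profile():
    half = 137.0 / 2.0
    assert boundary_rate_function(np.array([0.0, half]), "N", 10.0, 8.0) == (
        pytest.approx(8.0)
    )
    assert boundary_rate_function(np.array([0.0, 0.0]), "N", 10.0, 8.0) < 1e-6
    with pytest.raises(ValueError):
        boundary_rate_function(np.array([0.0, 0.0]), "N", -1.0, 8.0)
    with pytest.raises(ValueError):
        boundary_rate_function(np.array([0.0, 0.0]), "Q", 10.0, 8.0)


def test_boundary_cell_tracks_wall_through_rotation():
    """A wall-tracking field stays on the same platform wall after ROT70."""
    units = [UnitSpec((1, 1, 1, 1), "boundary", wall="N", width=12.0,
                      peak=10.0)]
    scene = gf.SceneConfig(manipulation="ROT70")
    sess = make_session(scene, units, duration=300.0, seed=8)
    st = sess.spike_trains[0]
    # recover platform-frame positions at spike times
    from gridframe.synthetic import camera_to_room, _rot_cw

    traj = sess.trajectory
    sx = np.interp(st.spike_times, traj.t, traj.x)
    sy = np.interp(st.spike_times, traj.t, traj.y)
    room = camera_to_room(scene, np.column_stack([sx, sy]))
    plat = (room - np.asarray(scene.translation_vector)) @ _rot_cw(
        scene.platform_rotation
    )
    dist_to_north = 137.0 / 2.0 - plat[:, 1]
    assert np.median(dist_to_north) < 18.0


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def test_zero_rate_yields_no_spikes():
    traj = simulate_trajectory(30.0, seed=9)
    st = generate_spikes(traj, lambda p: np.zeros(np.atleast_2d(p).shape[0]),
                         rate_max=1.0, seed=1)
    assert len(st) == 0


def test_constant_rate_poisson_count_concentration():
    traj = simulate_trajectory(60.0, seed=10)
    r, T = 20.0, traj.duration
    counts = [
        len(generate_spikes(traj, lambda p: np.full(np.atleast_2d(p).shape[0], r),
                            rate_max=r, seed=s))
        for s in range(20)
    ]
    assert abs(np.mean(counts) - r * T) < 4.0 * np.sqrt(r * T)
    first = generate_spikes(traj, lambda p: np.full(np.atleast_2d(p).shape[0], r),
                            rate_max=r, seed=0)
    again = generate_spikes(traj, lambda p: np.full(np.atleast_2d(p).shape[0], r),
                            rate_max=r, seed=0)
    np.testing.assert_array_equal(first.spike_times, again.spike_times)
    assert np.all(first.spike_times > traj.t[0])
    assert np.all(first.spike_times < traj.t[-1])


def test_thinning_matches_bernoulli_oracle():
    """Thinned spike counts match a 1-ms time-discretized Bernoulli oracle."""
    traj = simulate_trajectory(10.0, seed=11)
    truth = GridGroundTruth(scale=50.0, peak_rate=30.0)
    fn = lambda p: grid_rate_function(p, truth)
    n_rep = 150
    thin_counts = np.array([
        len(generate_spikes(traj, fn, truth.peak_rate, seed=s))
        for s in range(n_rep)
    ])
    # oracle: Bernoulli(rate * dt) on a 1 ms grid along the same path
    dt = 1e-3
    tt = np.arange(traj.t[0], traj.t[-1], dt)
    xs = np.interp(tt, traj.t, traj.x)
    ys = np.interp(tt, traj.t, traj.y)
    p = fn(np.column_stack([xs, ys])) * dt
    rng = np.random.default_rng(1234)
    oracle_counts = np.array([
        (rng.random(p.size) < p).sum() for _ in range(n_rep)
    ])
    se = np.sqrt(np.var(thin_counts) / n_rep + np.var(oracle_counts) / n_rep)
    assert abs(thin_counts.mean() - oracle_counts.mean()) < 4.0 * se


def test_rate_exceeding_bound_rejected():
    traj = simulate_trajectory(5.0, seed=12)
    with pytest.raises(ValueError):
        generate_spikes(traj, lambda p: np.full(np.atleast_2d(p).shape[0], 5.0),
                        rate_max=1.0, seed=0)
    with pytest.raises(ValueError):
        generate_spikes(traj, lambda p: np.full(np.atleast_2d(p).shape[0], -1.0),
                        rate_max=1.0, seed=0)


# ---------------------------------------------------------------------------
# manipulation algebra
# ---------------------------------------------------------------------------

def _scenes(manip):
    return gf.SceneConfig(manipulation="STD"), gf.SceneConfig(manipulation=manip)


def test_room_anchored_truth_unchanged_in_room_coordinates():
    truth = GridGroundTruth(anchoring="room", orientation=12.0, phase=(7, -4))
    std, m = _scenes("SHIFT")
    out = apply_manipulation(truth, std, m)
    rng = np.random.default_rng(2)
    pts = rng.uniform(-150, 150, size=(100, 2))
    np.testing.assert_allclose(grid_rate_function(pts, out),
                               grid_rate_function(pts, truth), atol=1e-12)


def test_platform_anchored_rot20_with_underrotation():
    truth = GridGroundTruth(anchoring="platform", orientation=7.0,
                            under_rotation=6.0)
    std, m = _scenes("ROT20")
    out = apply_manipulation(truth, std, m)
    # grid rotates 14 deg CW in the room: CCW orientation decreases by 14
    assert truth.orientation - out.orientation == pytest.approx(14.0)


def test_geometry_anchored_rot70_rotates_20_ccw():
    truth = GridGroundTruth(anchoring="geometry", orientation=0.0)
    std, m = _scenes("ROT70")
    out = apply_manipulation(truth, std, m)
    assert out.orientation - truth.orientation == pytest.approx(20.0)


def test_std_session_leaves_truth_unchanged():
    truth = GridGroundTruth(anchoring="platform", under_rotation=6.0,
                            phase=(5, 5))
    std, m = _scenes("STD2")
    out = apply_manipulation(truth, std, m)
    assert out.orientation == truth.orientation
    assert out.phase == truth.phase


def test_platform_anchored_shift_translates_phase_with_lag():
    truth = GridGroundTruth(anchoring="platform", phase=(5.0, 3.0),
                            phase_lag=(3.0, 0.0))
    std, m = _scenes("SHIFT")
    out = apply_manipulation(truth, std, m)
    assert out.phase == pytest.approx((5.0 + 68.5 - 3.0, 3.0))
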