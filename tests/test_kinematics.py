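import numpy as np
import pytest

from reachseq import SequenceGeometry, Target, Trajectory
from reachseq.kinematics import (
    CrossingError,
    fusion_index,
    halfway_cross,
    max_curvature_in_target,
    signed_curvature,
    split_segments,
    transitional_cross,
    trial_features,
)


def make_traj(xy, dt=0.01):
    xy = np.asarray(xy, float)
    return Trajectory(times=np.arange(len(xy)) * dt, positions=xy)


def circle_traj(radius=100.0, ccw=True, n=300):
    th = np.linspace(0, 2 * np.pi, n)
    if not ccw:
        th = -th
    xy = radius * np.column_stack([np.cos(th), np.sin(th)])
    return make_traj(xy)


def interior(curv):
    """Curvature samples away from the open ends of the sampled path."""
    vals = curv[2:-2]
    return vals[np.isfinite(vals)]


def test_circle_curvature_magnitude_and_sign():
    assert np.allclose(interior(signed_curvature(circle_traj(100.0))), 0.01, rtol=0.01)
    cw = interior(signed_curvature(circle_traj(100.0, ccw=False)))
    assert np.allclose(cw, -0.01, rtol=0.01)


def test_curvature_scales_inversely_with_radius():
    for radius in (50.0, 200.0):
        curv = interior(signed_curvature(circle_traj(radius)))
        assert np.median(curv) == pytest.approx(1.0 / radius, rel=0.01)


def test_curvature_nan_at_speed_floor():
    """Samples where the hand (nearly) stops have undefined curvature."""
    n = 101
    t = np.linspace(0, 1, n)
    # triangular profile pausing in the middle
    x = np.concatenate([np.linspace(0, 100, 46), np.full(9, 100.0),
                        np.linspace(100, 200, 46)])
    traj = Trajectory(times=t, positions=np.column_stack([x, np.zeros(n)]))
    curv = signed_curvature(traj, smooth_window=None)
    assert np.all(np.isnan(curv[48:53]))


def test_straight_line_zero_curvature():
    xy = np.column_stack([np.linspace(0, 100, 50), np.linspace(0, 50, 50)])
    curv = signed_curvature(make_traj(xy), smooth_window=None)
    assert np.allclose(curv[np.isfinite(curv)], 0.0, atol=1e-12)


def bulged_path(amplitude, n=201):
    """Start (0,0) to (0,200), bulging toward +x by `amplitude` mm."""
    s = np.linspace(0, 1, n)
    x = amplitude * np.sin(np.pi * s)
    y = 200.0 * s
    return make_traj(np.column_stack([x, y]))


def test_halfway_cross_sign_toward_next_target():
    p_from, p_to = np.zeros(2), np.array([0.0, 200.0])
    nxt = np.array([150.0, 250.0])  # next target on the +x side
    assert halfway_cross(bulged_path(+30), p_from, p_to, nxt) == pytest.approx(30, abs=0.1)
    assert halfway_cross(bulged_path(-30), p_from, p_to, nxt) == pytest.approx(-30, abs=0.1)
    # next target on the -x side flips the sign convention
    nxt_left = np.array([-150.0, 250.0])
    assert halfway_cross(bulged_path(+30), p_from, p_to, nxt_left) == pytest.approx(-30, abs=0.1)


def test_halfway_cross_no_next_target_left_positive():
    p_from, p_to = np.zeros(2), np.array([0.0, 200.0])
    # travel along +y: left of travel is -x
    assert halfway_cross(bulged_path(-30), p_from, p_to, None) == pytest.approx(30, abs=0.1)


def test_halfway_cross_uses_first_crossing():
    """An S-shaped path crossing the halfway line twice scores the first."""
    s = np.linspace(0, 1, 401)
    x = 20 * np.sin(2 * np.pi * s)  # +20 bulge before midline, -20 after
    y = 200.0 * s
    traj = make_traj(np.column_stack([x, y]))
    val = halfway_cross(traj, np.zeros(2), np.array([0.0, 200.0]), np.array([1.0, 100.0]))
    assert val == pytest.approx(0.0, abs=1e-6)  # crosses exactly at the midline


def test_halfway_cross_errors():
    traj = bulged_path(10)
    with pytest.raises(ValueError):
        halfway_cross(traj, np.zeros(2), np.zeros(2))  # coincident endpoints
    short = make_traj([[0, 0], [0, 10], [0, 20]])
    with pytest.raises(CrossingError):
        halfway_cross(short, np.zeros(2), np.array([0.0, 200.0]))


def cutting_path(n=201):
    """(0,0) -> (150,200) cutting the corner at (0,200) on the inside."""
    s = np.linspace(0, 1, n)[:, None]
    p0, p2 = np.array([[0.0, 0.0]]), np.array([[150.0, 200.0]])
    ctrl = np.array([[28.0, 172.0]])  # inside the turn
    return make_traj((1 - s) ** 2 * p0 + 2 * (1 - s) * s * ctrl + s**2 * p2)


def overshoot_path():
    """(0,0) -> past the corner on the outside (beyond y=200, left of the
    target) before turning toward (150,200)."""
    up = np.linspace([0.0, 0.0], [-5.0, 230.0], 101)
    back = np.linspace([-5.0, 230.0], [150.0, 200.0], 101)[1:]
    return make_traj(np.vstack([up, back]))


def test_transitional_cross_sign():
    p_prev, p_tgt, p_next = np.zeros(2), np.array([0.0, 200.0]), np.array([150.0, 200.0])
    inside = transitional_cross(cutting_path(), p_prev, p_tgt, p_next)
    outside = transitional_cross(overshoot_path(), p_prev, p_tgt, p_next)
    assert inside > 0 > outside


def test_transitional_cross_degenerate_straight_geometry():
    """Nearly collinear waypoints fall back to the travel normal; the
    measurement is then a plain lateral offset and must not blow up."""
    p_prev, p_tgt, p_next = np.zeros(2), np.array([0.0, 200.0]), np.array([0.0, 400.0])
    s = np.linspace(0, 1, 401)
    xy = np.column_stack([5.0 * np.sin(np.pi * s), 400.0 * s])
    val = transitional_cross(make_traj(xy), p_prev, p_tgt, p_next)
    assert np.isfinite(val) and abs(val) < 10


def speed_profile_traj(vmin_frac, vpeak=700.0, dt=0.01):
    """1-D path through two targets with per-segment peak `vpeak` and a dip
    to `vmin_frac * vpeak` at the first target (x = 200)."""
    n = 201
    s = np.linspace(0, 1, n)
    v = vpeak * (vmin_frac + (1 - vmin_frac) * np.sin(np.pi * ((2 * s) % 1.0)) ** 2)
    x = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
    x *= 400.0 / x[-1]  # end exactly at the second target center
    return Trajectory(times=np.arange(n) * dt, positions=np.column_stack([x, np.zeros(n)]))


@pytest.fixture(scope="module")
def two_target_geom():
    return SequenceGeometry(
        start=(0.0, 0.0),
        targets=(Target((200.0, 0.0), 35.0, "t1"), Target((400.0, 0.0), 35.0, "t2")),
    )


def test_fusion_index_analytic_cases(two_target_geom):
    for frac, expected in ((1.0, 1.0), (0.5, 0.5), (0.0, 0.0)):
        traj = speed_profile_traj(frac)
        assert fusion_index(traj, 0, two_target_geom) == pytest.approx(expected, abs=0.05)


def test_fusion_index_bounds_and_errors(two_target_geom):
    traj = speed_profile_traj(0.7)
    f = fusion_index(traj, 0, two_target_geom)
    assert 0.0 <= f <= 1.0
    with pytest.raises(ValueError):
        fusion_index(traj, 1, two_target_geom)  # last target is not intermediate


def test_split_segments_partitions(two_target_geom):
    traj = speed_profile_traj(0.2)
    split = split_segments(traj, two_target_geom)
    assert len(split.segment_slices) == 2
    (a0, b0), (a1, b1) = split.segment_slices
    assert a0 == 0 and b0 == a1 and b1 == traj.n_samples - 1
    # split lands at the speed minimum, inside the first target
    idx = split.split_indices[0]
    assert two_target_geom.targets[0].contains(traj.positions[idx])
    for nt in split.normalized_times:
        assert nt[0] == 0.0 and nt[-1] == pytest.approx(1.0)


def test_split_segments_missing_target(two_target_geom):
    xy = np.column_stack([np.linspace(0, 100, 50), np.zeros(50)])  # never reaches t1
    with pytest.raises(ValueError, match="does not visit"):
        split_segments(make_traj(xy), two_target_geom)


def test_max_curvature_in_target_requires_visit(two_target_geom):
    xy = np.column_stack([np.linspace(0, 100, 50), np.zeros(50)])
    with pytest.raises(ValueError, match="never enters"):
        max_curvature_in_target(make_traj(xy), two_target_geom.targets[0])


def test_trial_features_keys_on_simulated_trial(geom0, quiet_plant):
    from reachseq import plan_sequence, simulate_vpsoc

    matrices, _, sol = plan_sequence(geom0, quiet_plant, h=(4.0, 4.0, 4.0), r=1e-7)
    (traj,) = simulate_vpsoc(sol, matrices, geom0, quiet_plant, noise_on=False)
    feats = trial_features(traj, geom0)
    for key in ("hc1", "tc1", "maxcurv1", "maxcurv2", "fusion1", "fusion2"):
        assert key in feats
    assert np.isfinite(feats["hc1"]) and np.isfinite(feats["maxcurv2"])
    assert 0.0 <= feats["fusion1"] <= 1.0 or np.isnan(feats["fusion1"])


def test_features_mirror_invariant(layout, quiet_plant):
    """Sequence 4 (red-pink) mirrors sequence 0 (blue-olive) about the
    midline; deterministic trials must give identical features."""
    from reachseq import plan_sequence, simulate_vpsoc

    vals = {}
    for sid in (0, 4):
        geom = layout.sequence_geometry(sid)
        matrices, _, sol = plan_sequence(geom, quiet_plant, h=(3.0, 2.0, 2.0), r=1e-6)
        (traj,) = simulate_vpsoc(sol, matrices, geom, quiet_plant, noise_on=False)
        vals[sid] = trial_features(traj, geom)
    for key in ("hc1", "tc1", "maxcurv1", "maxcurv2"):
        assert vals[0][key] == pytest.approx(vals[4][key], rel=1e-6, abs=1e-9)
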