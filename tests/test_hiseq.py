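import numpy as np
import pytest

from reachseq import PlantParams
from reachseq.hiseq import (
    SHCParams,
    SHCState,
    Z_FLOOR,
    build_hiseq_plan,
    make_shc_connectivity,
    mix_commands,
    monitor,
    shc_step,
    simulate_hiseq,
)
from reachseq.geometry import SequenceGeometry, Target


def test_connectivity_recipe_shapes():
    shc = make_shc_connectivity(2)
    assert shc.n_z == 2
    assert np.all(np.diag(shc.rho) == 1.0)
    assert shc.rho[1, 0] < 1 < shc.rho[0, 1]


def test_connectivity_validation():
    with pytest.raises(ValueError):
        make_shc_connectivity(1)
    with pytest.raises(ValueError):
        make_shc_connectivity(2, rho_next=1.2)  # breaks the saddle recipe
    with pytest.raises(ValueError):
        make_shc_connectivity(2, rho_other=0.5)


def test_params_validation():
    with pytest.raises(ValueError):
        SHCParams(alpha=np.array([1.0, -1.0]), rho=np.eye(2))
    with pytest.raises(ValueError):
        SHCParams(alpha=np.ones(2), rho=np.eye(3))
    with pytest.raises(ValueError):
        SHCParams(alpha=np.ones(2), rho=np.eye(2), pulse_mode="bogus")


def test_equilibria_are_fixed_points_noise_off():
    """Every one-hot equilibrium is a fixed point: the one-step displacement
    is at the numerical floor (saddles are unstable, so any finite offset
    grows -- the *equilibrium itself* must not move); the final equilibrium is
    additionally stable over a long noise-free run."""
    shc = make_shc_connectivity(3, eta_base=0.0)
    for i in range(3):
        z0 = shc.equilibrium(i)
        s = shc_step(SHCState(z=z0.copy()), shc, eta_pulse=0.0, rng=None)
        assert np.max(np.abs(s.z - z0)) < 1e-6
    z_last = shc.equilibrium(2)
    s = SHCState(z=z_last.copy())
    for _ in range(500):
        s = shc_step(s, shc, eta_pulse=0.0, rng=None)
    assert np.max(np.abs(s.z - z_last)) < 1e-4


def test_saddle_structure_eigenvalues():
    """Every non-final equilibrium has exactly one unstable direction."""
    from reachseq.hiseq import _lv_jacobian

    shc = make_shc_connectivity(2)
    eig0 = np.linalg.eigvals(_lv_jacobian(shc.equilibrium(0), shc)).real
    eig1 = np.linalg.eigvals(_lv_jacobian(shc.equilibrium(1), shc)).real
    assert np.sum(eig0 > 1e-9) == 1
    assert np.all(eig1 <= 1e-9)


def test_noisy_step_requires_rng():
    shc = make_shc_connectivity(2)
    with pytest.raises(ValueError):
        shc_step(SHCState(z=shc.equilibrium(0)), shc, eta_pulse=1.0, rng=None)


def test_step_respects_floor():
    shc = make_shc_connectivity(2)
    s = SHCState(z=np.array([Z_FLOOR, Z_FLOOR]))
    s = shc_step(s, shc, rng=np.random.default_rng(0))
    assert np.all(s.z >= Z_FLOOR)


def test_mix_commands_weighted_sum():
    z = np.array([0.5, 0.25])
    alpha = np.array([1.0, 0.5])
    u = [np.array([2.0, 0.0]), np.array([0.0, 4.0])]
    out = mix_commands(z, alpha, u)
    assert np.allclose(out, [1.0, 2.0])
    with pytest.raises(ValueError):
        mix_commands(z, alpha, u[:1])


def test_monitor_trigger_radius():
    shc = make_shc_connectivity(2, monitor_sd=10.0, monitor_distance=1.0)
    tgt = Target((0.0, 0.0), 50.0, "t")
    assert monitor(np.array([0.0, 49.0]), tgt, shc) == 10.0
    assert monitor(np.array([0.0, 50.0]), tgt, shc) == 10.0  # boundary inclusive
    assert monitor(np.array([0.0, 51.0]), tgt, shc) == 0.0


def test_plan_structure(geom0, plant):
    plan = build_hiseq_plan(geom0, plant, h=(2.0, 2.0, 2.0), r=1e-6)
    assert len(plan.controllers) == 2
    assert plan.attractor_map == (0, 1)
    # sub-goals: each block's final target
    assert plan.attractor_targets[0].label == geom0.targets[1].label
    assert plan.attractor_targets[1].label == geom0.targets[2].label
    assert plan.horizon == 210
    # the 2-target block plans on a shorter horizon, the return block on the
    # global clock
    assert plan.controllers[0].T == 140
    assert plan.controllers[1].T == 210


def test_plan_requires_three_targets(plant):
    geo = SequenceGeometry(start=(0.0, 0.0), targets=(Target((0, 100), 30, "a"),))
    with pytest.raises(ValueError):
        build_hiseq_plan(geo, plant)


def test_hold_attractor_degenerates_to_subcontroller(geom0, quiet_plant):
    """Pinned at attractor 0 the hand runs the 2-target block and never goes
    home; pinned at 1 it (trivially) stays near the start's home plan."""
    plan = build_hiseq_plan(geom0, quiet_plant, h=(4.0, 4.0, 4.0), r=1e-7)
    shc = make_shc_connectivity(2)
    (tr0,) = simulate_hiseq(plan, shc, quiet_plant, hold_attractor=0, noise_on=False)
    # visits targets 1 and 2 but does not return home at the end
    assert np.any(geom0.targets[0].contains(tr0.positions))
    assert np.any(geom0.targets[1].contains(tr0.positions))
    home = geom0.targets[2]
    assert not home.contains(tr0.positions[-1])
    (tr1,) = simulate_hiseq(plan, shc, quiet_plant, hold_attractor=1, noise_on=False)
    assert home.contains(tr1.positions[-1])
    assert not np.any(geom0.targets[0].contains(tr1.positions))


def test_simulation_reproducible(geom0, plant):
    plan = build_hiseq_plan(geom0, plant, h=(2.0, 2.0, 2.0), r=1e-6)
    shc = make_shc_connectivity(2)
    a = simulate_hiseq(plan, shc, plant, n_trials=3, seed=7)
    b = simulate_hiseq(plan, shc, plant, n_trials=3, seed=7)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.positions, tb.positions)


def test_stuck_flag_without_monitor(geom0, plant):
    """With the monitor silenced, baseline noise alone cannot trigger the
    hand-off within the trial; trials end stuck at the first attractor."""
    plan = build_hiseq_plan(geom0, plant, h=(2.0, 2.0, 2.0), r=1e-6)
    shc = make_shc_connectivity(2, monitor_sd=0.0)
    trials = simulate_hiseq(plan, shc, plant, n_trials=5, seed=3)
    assert all(t.meta["stuck"] for t in trials)


def test_activations_recorded(geom0, plant):
    plan = build_hiseq_plan(geom0, plant, h=(2.0, 2.0, 2.0), r=1e-6)
    shc = make_shc_connectivity(2)
    (tr,) = simulate_hiseq(plan, shc, plant, seed=11, record_activations=True)
    z = tr.meta["activations"]
    assert z.shape == (plan.horizon + 1, 2)
    assert np.all(z >= Z_FLOOR)
    # starts at the first attractor, ends at the second
    assert np.argmax(z[0]) == 0
    if not tr.meta["stuck"]:
        assert np.argmax(z[-1]) == 1


def test_handoff_produces_sequence(geom0, plant):
    """With the monitor active, trials visit all three targets in order."""
    from reachseq.kinematics import split_segments

    plan = build_hiseq_plan(geom0, plant, h=(2.0, 2.0, 2.0), r=1e-6)
    shc = make_shc_connectivity(2)
    trials = simulate_hiseq(plan, shc, plant, n_trials=10, seed=21)
    ok = 0
    for t in trials:
        if t.meta["stuck"]:
            continue
        try:
            split_segments(t, geom0)
            ok += 1
        except ValueError:
            pass
    assert ok >= 8
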