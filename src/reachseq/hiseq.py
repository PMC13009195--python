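"""Hierarchical sequential controller (HiSeq).

Three layers compose a multi-target reaching sequence at run time:

* bottom: via-point optimal controllers (vpSOC building blocks) for one- and
  two-target movements, each with its own Kalman estimator;
* middle: a generalized Lotka-Volterra system whose activations ``z`` follow
  a stable heteroclinic channel (SHC) -- a chain of saddle equilibria visited
  in a fixed order, robust to noise;
* top: the sequence itself, realized as the SHC connectivity (``alpha``,
  ``rho``); it has no dynamics within a trial.

Motor commands are the activation-weighted sum of the sub-controllers'
commands, ``u = sum_i (z_i / alpha_i) u^(map(i))``.  A monitor inside the SHC
layer injects a noise pulse into the activation dynamics whenever the hand is
within the current sub-goal's circle, kicking the state off the current
saddle and onto the next; during the brief hand-off both controllers are
active, which is what produces transitional coarticulation around the
intermediate target.

The canonical 3-target configuration uses one attractor per sub-controller:
a vpSOC(2) drives the first two targets and a vpSOC(1) takes over for the
return, so the SHC has two attractors mapped ``(0, 1)``.  Each attractor's
sub-goal is the final target of its own sub-controller: the monitor fires
when the hand completes the two-target block (enters the second target) and
hands control to the return block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SequenceGeometry, Target
from .plant import PlantMatrices, PlantParams
from .trajectory import Trajectory
from .vpsoc import (
    ControlSolution,
    build_bias_plant,
    build_cost,
    solve_lqg,
)

__all__ = [
    "SHCParams",
    "SHCState",
    "SubController",
    "HiSeqPlan",
    "make_shc_connectivity",
    "shc_step",
    "mix_commands",
    "monitor",
    "build_hiseq_plan",
    "simulate_hiseq",
]

#: positivity floor for the Lotka-Volterra activations
Z_FLOOR = 1e-6


@dataclass(frozen=True)
class SHCParams:
    """Lotka-Volterra connectivity and monitor settings.

    ``tau`` is the SHC rate constant (default 33 /s); ``eta_base`` a small
    baseline noise amplitude; ``monitor_distance`` the pulse trigger radius
    as a fraction of the target radius; ``monitor_sd`` the pulse amplitude
    (5 or 10 in the canonical settings)."""

    alpha: np.ndarray
    rho: np.ndarray
    tau: float = 33.0
    eta_base: float = 1e-4
    monitor_distance: float = 1.0
    monitor_sd: float = 10.0
    dt: float = 0.01
    pulse_mode: str = "sustained"  # or "oneshot"
    #: stop pulsing once the next activation exceeds this level: the pulse's
    #: job is to seed the escape from the saddle, and further kicks would
    #: perturb the hand-off itself
    pulse_cutoff: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be elementwise positive")
        if self.rho.shape != (self.n_z, self.n_z):
            raise ValueError("rho must be square, matching alpha")
        if self.monitor_distance <= 0:
            raise ValueError("monitor_distance must be positive")
        if self.pulse_mode not in ("sustained", "oneshot"):
            raise ValueError("pulse_mode must be 'sustained' or 'oneshot'")

    @property
    def n_z(self) -> int:
        return self.alpha.shape[0]

    def equilibrium(self, i: int) -> np.ndarray:
        """One-hot equilibrium: z_i = alpha_i / rho_ii, others at the floor."""
        z = np.full(self.n_z, Z_FLOOR)
        z[i] = self.alpha[i] / self.rho[i, i]
        return z


@dataclass
class SHCState:
    z: np.ndarray
    active: int = 0
    t: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if np.any(self.z < 0):
            raise ValueError("activations must be non-negative")


def make_shc_connectivity(
    sequence_length: int,
    tau: float = 33.0,
    rho_next: float = 0.85,
    rho_other: float = 1.5,
    **kwargs,
) -> SHCParams:
    """Asymmetric-inhibition recipe producing a saddle chain.

    Each one-hot equilibrium except the last is a saddle whose single
    unstable direction points to the next attractor (``rho[next, i] < 1``);
    all other cross-inhibitions exceed 1, and the final equilibrium is
    stable.  The construction is validated by an eigenvalue check of the
    Jacobian at every equilibrium.

    The escape rate of a triggered transition is ``tau * (1 - rho_next)``
    (about 5 /s with the defaults): fast enough that a monitor-triggered
    hand-off completes within ~0.2-0.3 s, while the unstable direction
    amplifies the baseline noise slowly enough that untriggered escapes are
    rare within a trial.
    """
    if sequence_length < 2:
        raise ValueError("need at least 2 attractors for a sequence")
    if not (0 < rho_next < 1 < rho_other):
        raise ValueError("recipe requires rho_next < 1 < rho_other")
    n = sequence_length
    alpha = np.ones(n)
    rho = np.full((n, n), rho_other)
    np.fill_diagonal(rho, 1.0)
    for i in range(n - 1):
        rho[i + 1, i] = rho_next
    params = SHCParams(alpha=alpha, rho=rho, tau=tau, **kwargs)
    _validate_saddle_chain(params)
    return params


def _lv_jacobian(z: np.ndarray, params: SHCParams) -> np.ndarray:
    a, rho, tau = params.alpha, params.rho, params.tau
    growth = a - rho @ z
    return tau * (np.diag(growth) - z[:, None] * rho)


def _validate_saddle_chain(params: SHCParams) -> None:
    n = params.n_z
    for i in range(n):
        J = _lv_jacobian(params.equilibrium(i), params)
        eig = np.linalg.eigvals(J).real
        n_unstable = int(np.sum(eig > 1e-9))
        if i < n - 1 and n_unstable != 1:
            raise ValueError(
                f"equilibrium {i} has {n_unstable} unstable directions, expected 1"
            )
        if i == n - 1 and n_unstable != 0:
            raise ValueError("final equilibrium must be stable")


def shc_step(
    state: SHCState,
    params: SHCParams,
    eta_pulse: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SHCState:
    """One explicit Euler step of the Lotka-Volterra activations.

    The noise term eta is part of the activation derivative, so its Euler
    contribution is ``dt * (eta_base + eta_pulse) * N(0, 1)`` on every
    component (the pulse is not component-specific); the result is clipped
    at the positivity floor."""
    z = state.z
    if not np.all(np.isfinite(z)):
        raise FloatingPointError(f"non-finite SHC state at t={state.t}: {z}")
    dz = params.dt * params.tau * z * (params.alpha - params.rho @ z)
    amp = params.eta_base + eta_pulse
    if amp > 0:
        if rng is None:
            raise ValueError("noisy SHC step requires an rng")
        dz = dz + params.dt * amp * rng.standard_normal(z.shape)
    z_new = np.maximum(z + dz, Z_FLOOR)
    active = int(np.argmax(z_new / params.alpha))
    return SHCState(z=z_new, active=active, t=state.t + 1)


def mix_commands(z: np.ndarray, alpha: np.ndarray, u_list: list[np.ndarray]) -> np.ndarray:
    """Activation-weighted motor command, ``sum_i (z_i/alpha_i) u_i``."""
    z = np.asarray(z, float)
    alpha = np.asarray(alpha, float)
    if np.any(alpha == 0):
        raise ValueError("alpha entries must be nonzero")
    if len(u_list) != z.shape[0]:
        raise ValueError("need one command per activation")
    w = z / alpha
    return sum(wi * np.asarray(ui, float) for wi, ui in zip(w, u_list))


def monitor(hand_pos: np.ndarray, current_target: Target, params: SHCParams) -> float:
    """Pulse amplitude: ``monitor_sd`` while the hand is within
    ``monitor_distance`` target radii of the center (boundary inclusive)."""
    d = np.linalg.norm(np.asarray(hand_pos, float) - current_target.center_arr)
    if d <= params.monitor_distance * current_target.radius:
        return params.monitor_sd
    return 0.0


@dataclass(frozen=True)
class SubController:
    """A vpSOC building block: gains plus the geometry it was solved for."""

    solution: ControlSolution
    geometry: SequenceGeometry

    @property
    def T(self) -> int:
        return self.solution.T


@dataclass(frozen=True)
class HiSeqPlan:
    """Ordered sub-controllers plus the attractor -> controller map.

    ``attractor_targets`` lists the sub-goal circle associated with each
    attractor (what the monitor watches while that attractor is active)."""

    controllers: tuple[SubController, ...]
    attractor_map: tuple[int, ...]
    attractor_targets: tuple[Target, ...]
    geometry: SequenceGeometry
    horizon: int

    def __post_init__(self) -> None:
        if len(self.attractor_map) != len(self.attractor_targets):
            raise ValueError("one sub-goal target per attractor")
        if any(i >= len(self.controllers) for i in self.attractor_map):
            raise ValueError("attractor_map indexes beyond the controllers")


def build_hiseq_plan(
    geometry: SequenceGeometry,
    params: PlantParams,
    h: tuple[float, ...] | None = None,
    r: float = 1e-5,
    duration_per_target: float = 0.7,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> HiSeqPlan:
    """Canonical plan for a 3-target sequence: vpSOC(2) + vpSOC(1).

    The vpSOC(2) covers targets 1-2 on its own 2-target horizon; the
    vpSOC(1)'s gains are indexed by global trial time (its single via-point
    is the trial end), so the hand-off is well-defined whenever the
    transition happens.  One attractor per sub-controller, mapped ``(0, 1)``,
    with sub-goals at each block's final target (target 2 and target 3).
    """
    if geometry.n_targets != 3:
        raise ValueError("the canonical HiSeq plan expects 3 targets")
    if h is None:
        h = (1.0, 1.0, 1.0)
    if len(h) != 3:
        raise ValueError("need one h per target")
    matrices = build_bias_plant(params)

    geo12 = SequenceGeometry(
        start=geometry.start,
        targets=geometry.targets[:2],
        sequence_id=geometry.sequence_id,
    )
    cost12 = build_cost(
        geo12, params, duration_per_target=duration_per_target, h=h[:2], r=r
    )
    sol12 = solve_lqg(
        matrices, cost12, params, tol=tol, max_iter=max_iter,
        x0=matrices.initial_state(geometry.start_arr),
    )

    steps_per = int(round(duration_per_target / params.delta))
    horizon = steps_per * 3
    geo3 = SequenceGeometry(
        start=geometry.start,
        targets=geometry.targets[2:],
        sequence_id=geometry.sequence_id,
    )
    cost3 = build_cost(
        geo3, params, duration_per_target=duration_per_target, h=h[2:], r=r,
        start_step=horizon - steps_per,
    )
    sol3 = solve_lqg(
        matrices, cost3, params, tol=tol, max_iter=max_iter,
        x0=matrices.initial_state(geometry.start_arr),
    )

    return HiSeqPlan(
        controllers=(SubController(sol12, geo12), SubController(sol3, geo3)),
        attractor_map=(0, 1),
        attractor_targets=(geometry.targets[1], geometry.targets[2]),
        geometry=geometry,
        horizon=horizon,
    )


def simulate_hiseq(
    plan: HiSeqPlan,
    shc: SHCParams,
    params: PlantParams,
    n_trials: int = 1,
    seed: int | None = None,
    noise_on: bool = True,
    hold_attractor: int | None = None,
    tag: str = "hiseq",
    record_activations: bool = False,
) -> list[Trajectory]:
    """Simulate closed-loop HiSeq trials on a shared plant.

    Every sub-controller keeps its own estimator running for the whole trial
    (it receives the shared observations even when its mixing weight is ~0),
    so the hand-off is state-consistent.  ``hold_attractor`` pins the SHC at
    one equilibrium with no noise (diagnostic: mixing degenerates to that
    attractor's sub-controller).  Trials where the SHC never reaches the
    final attractor are flagged with ``meta['stuck'] = True``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seed is None and (noise_on or hold_attractor is None):
        raise ValueError("a seed is required for stochastic simulation")
    rng = np.random.default_rng(seed)
    matrices = build_bias_plant(params)
    A, B, C, H = matrices.A, matrices.B, matrices.C, matrices.H
    n_z = shc.n_z
    n_ctl = len(plan.controllers)
    T = plan.horizon
    obs_sd = np.sqrt(np.diag(params.obs_covariance()))
    add_sd = np.sqrt(params.add_noise)
    from .plant import IDX_G, N_BLOCK

    g_idx = [d * N_BLOCK + IDX_G for d in range(params.n_dims)]

    x0 = matrices.initial_state(plan.geometry.start_arr)
    x = np.tile(x0, (n_trials, 1))
    xhat = np.stack([x.copy() for _ in range(n_ctl)])  # (n_ctl, n_trials, S)

    if hold_attractor is not None:
        z = np.tile(shc.equilibrium(hold_attractor), (n_trials, 1))
    else:
        z = np.tile(shc.equilibrium(0), (n_trials, 1))
    pulsed = np.zeros((n_trials, n_z), dtype=bool)  # for one-shot mode

    pos = np.empty((n_trials, T + 1, 2))
    pos[:, 0] = matrices.positions(x)
    zrec = np.empty((n_trials, T + 1, n_z)) if record_activations else None
    if record_activations:
        zrec[:, 0] = z

    for t in range(T):
        # sub-controller commands from their own estimators
        u_sub = np.empty((n_ctl, n_trials, params.n_dims))
        for c, ctl in enumerate(plan.controllers):
            tc = min(t, ctl.T - 1)
            u_sub[c] = -(xhat[c] @ ctl.solution.L[tc].T)
        w = z / shc.alpha  # (n_trials, n_z)
        u = np.zeros((n_trials, params.n_dims))
        for i, c in enumerate(plan.attractor_map):
            u += w[:, i : i + 1] * u_sub[c]

        # monitor: pulse while inside the active attractor's sub-goal circle
        if hold_attractor is None:
            active = np.argmax(w, axis=1)
            hand = matrices.positions(x)
            pulse = np.zeros(n_trials)
            for i, tgt in enumerate(plan.attractor_targets):
                if i == n_z - 1:
                    continue  # final attractor: nothing left to trigger
                mask = active == i
                if not np.any(mask):
                    continue
                d = np.linalg.norm(hand[mask] - tgt.center_arr, axis=1)
                hit = d <= shc.monitor_distance * tgt.radius
                hit &= z[mask, i + 1] < shc.pulse_cutoff
                if shc.pulse_mode == "oneshot":
                    fresh = hit & ~pulsed[mask, i]
                    pulsed[np.flatnonzero(mask)[fresh], i] = True
                    hit = fresh
                pulse[np.flatnonzero(mask)[hit]] = shc.monitor_sd
            # Lotka-Volterra Euler-Maruyama step, vectorized over trials
            dz = shc.dt * shc.tau * z * (shc.alpha - z @ shc.rho.T)
            amp = (shc.eta_base if noise_on else 0.0) + pulse[:, None]
            if np.any(amp > 0):
                dz = dz + shc.dt * amp * rng.standard_normal(z.shape)
            z = np.maximum(z + dz, Z_FLOOR)

        # shared plant and observations
        y = x @ H.T
        if noise_on:
            y = y + obs_sd * rng.standard_normal(y.shape)
        for c, ctl in enumerate(plan.controllers):
            tc = min(t, ctl.T - 1)
            innov = y - xhat[c] @ H.T
            xhat[c] = xhat[c] @ A.T + u @ B.T + innov @ ctl.solution.K[tc].T
        x = x @ A.T + u @ B.T
        if noise_on:
            eps = rng.standard_normal(u.shape)
            x = x + (u * eps) @ C.T
            if add_sd > 0:
                x[:, g_idx] += add_sd * rng.standard_normal((n_trials, len(g_idx)))
        pos[:, t + 1] = matrices.positions(x)
        if record_activations:
            zrec[:, t + 1] = z

    final_w = z / shc.alpha
    stuck = np.argmax(final_w, axis=1) != n_z - 1 if hold_attractor is None else np.zeros(n_trials, bool)

    times = np.arange(T + 1) * params.delta
    out = []
    for i in range(n_trials):
        meta = {"stuck": bool(stuck[i])}
        if record_activations:
            meta["activations"] = zrec[i]
        out.append(
            Trajectory(
                times=times,
                positions=pos[i],
                trial=i,
                sequence_id=plan.geometry.sequence_id,
                tag=tag,
                meta=meta,
            )
        )
    return out
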