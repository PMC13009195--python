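"""Via-point stochastic optimal controller (vpSOC).

A whole reaching sequence is planned as a single finite-horizon LQG problem
with signal-dependent motor noise.  Each target is a via-point: at its
prescribed step ``t_i`` the state cost ``Q_{t_i} = h_i^2 p p^T + f f^T +
v v^T`` penalizes distance of the hand from the target center (weighted by
the per-target precision ``h_i``) together with residual speed and force
(weights ``omega_v``, ``omega_f``, applied at every via-point, not only the
final one).  The energy cost is ``r ||u||^2`` at every step.

Because the plant is linear with multiplicative control noise, the optimal
feedback gains ``L_t`` and Kalman gains ``K_t`` are coupled; they are found
by alternating a backward control recursion (given the filter gains) and a
forward filter recursion (given the control gains) until the gains stop
changing.  With the signal-dependent and additive noise switched off this
reduces exactly to the classical discrete-time finite-horizon LQR/Kalman
solution.

Target encoding: the plant's constant ``xi`` block is used as a unit bias
(``xi = 1`` per dimension) so that a single block can express the distance to
*any* via-point's center: the cost vector for via-point ``i`` in dimension
``d`` is ``+1`` on ``p_d`` and ``-c_i[d]`` on ``xi_d``, giving
``p_d - c_i[d]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SequenceGeometry, Target
from .plant import IDX_F, IDX_P, IDX_V, N_BLOCK, PlantMatrices, PlantParams, build_plant
from .trajectory import Trajectory

__all__ = [
    "SequenceGeometry",
    "Target",
    "ViaPointCost",
    "ControlSolution",
    "build_bias_plant",
    "build_cost",
    "solve_lqg",
    "simulate_vpsoc",
    "plan_sequence",
]

DEFAULT_OMEGA_V = 0.4
DEFAULT_OMEGA_F = 0.6
DEFAULT_DURATION_PER_TARGET = 0.7  # s


@dataclass(frozen=True)
class ViaPointCost:
    """Sparse time-indexed state costs for a via-point sequence."""

    via_steps: tuple[int, ...]
    Q_via: tuple[np.ndarray, ...]  # one (S, S) matrix per via-point
    h: tuple[float, ...]
    omega_v: float
    omega_f: float
    r: float
    T: int
    n_dims: int

    def __post_init__(self) -> None:
        steps = self.via_steps
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("via-point steps must be strictly increasing")
        if steps[-1] != self.T:
            raise ValueError("last via-point must coincide with the horizon")
        if any(hi < 0 for hi in self.h):
            raise ValueError("precision weights h must be non-negative")

    def Q_full(self, n_states: int) -> np.ndarray:
        """Dense (T + 1, S, S) cost array (zero except at via-points)."""
        Q = np.zeros((self.T + 1, n_states, n_states))
        for t, q in zip(self.via_steps, self.Q_via):
            Q[t] = q
        return Q

    def R(self) -> np.ndarray:
        return self.r * np.eye(self.n_dims)


@dataclass
class ControlSolution:
    """Time series of feedback and filter gains from the coupled iteration."""

    L: np.ndarray  # (T, n_controls, n_states)
    K: np.ndarray  # (T, n_states, n_obs)
    iterations: int
    converged: bool
    expected_cost: float

    @property
    def T(self) -> int:
        return self.L.shape[0]


def build_bias_plant(params: PlantParams) -> PlantMatrices:
    """Plant whose ``xi`` block is a constant unit bias (see module docs)."""
    return build_plant(params, np.ones(params.n_dims))


def build_cost(
    geometry: SequenceGeometry,
    params: PlantParams,
    duration_per_target: float = DEFAULT_DURATION_PER_TARGET,
    h: tuple[float, ...] | list[float] | None = None,
    r: float = 1e-5,
    omega_v: float = DEFAULT_OMEGA_V,
    omega_f: float = DEFAULT_OMEGA_F,
    *,
    start_step: int = 0,
) -> ViaPointCost:
    """Build via-point costs for ``geometry``, one via-point per target.

    Via-point times are equally spaced at ``duration_per_target`` (default
    0.7 s per target); the last via-point is the horizon.  ``start_step``
    offsets all via times, for sub-controllers whose clock starts at trial
    start but whose first via-point lies later.
    """
    if duration_per_target <= 0:
        raise ValueError("duration_per_target must be positive")
    n_targets = geometry.n_targets
    if h is None:
        h = tuple(1.0 for _ in range(n_targets))
    h = tuple(float(v) for v in h)
    if len(h) != n_targets:
        raise ValueError(f"need one h per target ({n_targets}), got {len(h)}")

    steps_per = int(round(duration_per_target / params.delta))
    via_steps = tuple(start_step + steps_per * (i + 1) for i in range(n_targets))
    T = via_steps[-1]
    S = params.n_states
    n = params.n_dims
    idx_xi = [d * N_BLOCK + N_BLOCK - 1 for d in range(n)]

    Q_via = []
    for i, tgt in enumerate(geometry.targets):
        q = np.zeros((S, S))
        c = tgt.center_arr
        for d in range(n):
            p_vec = np.zeros(S)
            p_vec[d * N_BLOCK + IDX_P] = 1.0
            p_vec[idx_xi[d]] = -c[d]
            q += h[i] ** 2 * np.outer(p_vec, p_vec)
            v_vec = np.zeros(S)
            v_vec[d * N_BLOCK + IDX_V] = omega_v
            q += np.outer(v_vec, v_vec)
            f_vec = np.zeros(S)
            f_vec[d * N_BLOCK + IDX_F] = omega_f
            q += np.outer(f_vec, f_vec)
        Q_via.append(q)

    return ViaPointCost(
        via_steps=via_steps,
        Q_via=tuple(Q_via),
        h=h,
        omega_v=omega_v,
        omega_f=omega_f,
        r=float(r),
        T=T,
        n_dims=n,
    )


def _solve_psd(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``mat @ X = rhs`` with a pseudo-inverse fallback."""
    try:
        return np.linalg.solve(mat, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(mat) @ rhs


def solve_lqg(
    matrices: PlantMatrices,
    cost: ViaPointCost,
    params: PlantParams,
    tol: float = 1e-8,
    max_iter: int = 50,
    *,
    x0: np.ndarray | None = None,
    sigma0: np.ndarray | None = None,
    eta_cov: np.ndarray | None = None,
) -> ControlSolution:
    """Alternating controller/estimator iteration for the noisy LQG problem.

    ``x0`` is the initial (known) state used for the estimator's second-moment
    recursion; ``sigma0`` the initial estimation-error covariance (default
    zero: the start position is known); ``eta_cov`` the covariance of the
    estimator's internal noise (default zero).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    A, B, C, H = matrices.A, matrices.B, matrices.C, matrices.H
    S = A.shape[0]
    nu = B.shape[1]
    ny = H.shape[0]
    T = cost.T
    Q = cost.Q_full(S)
    R = cost.R()
    omega_xi = params.dynamics_covariance()
    omega_w = params.obs_covariance()
    omega_eta = np.zeros((S, S)) if eta_cov is None else np.asarray(eta_cov, float)
    if x0 is None:
        x0 = matrices.initial_state()
    sig0 = np.zeros((S, S)) if sigma0 is None else np.asarray(sigma0, float)

    def backward(K: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        L = np.zeros((T, nu, S))
        Sx = Q[T].copy()
        Se = np.zeros((S, S))
        s_scalar = 0.0
        for t in range(T - 1, -1, -1):
            # signal-dependent noise: per-channel columns of C
            sdn = np.array([C[:, i] @ (Sx + Se) @ C[:, i] for i in range(nu)])
            M = R + B.T @ Sx @ B + np.diag(sdn)
            Lt = _solve_psd(M, B.T @ Sx @ A)
            L[t] = Lt
            AK = A - K[t] @ H
            Se_new = A.T @ Sx @ B @ Lt + AK.T @ Se @ AK
            Sx_new = Q[t] + A.T @ Sx @ (A - B @ Lt)
            s_scalar += np.trace(
                Sx @ omega_xi + Se @ (omega_xi + omega_eta + K[t] @ omega_w @ K[t].T)
            )
            Sx, Se = Sx_new, Se_new
        expected = float(x0 @ Sx @ x0 + np.trace((Sx + Se) @ sig0) + s_scalar)
        return L, Sx, Se, expected

    def forward(L: np.ndarray) -> np.ndarray:
        K = np.zeros((T, S, ny))
        sig_e = sig0.copy()
        sig_x = np.outer(x0, x0)
        sig_xe = np.zeros((S, S))
        for t in range(T):
            innov = H @ sig_e @ H.T + omega_w
            K[t] = _solve_psd(innov.T, (A @ sig_e @ H.T).T).T
            Lt = L[t]
            ABL = A - B @ Lt
            AKH = A - K[t] @ H
            lsl = Lt @ sig_x @ Lt.T
            sdn = sum(lsl[i, i] * np.outer(C[:, i], C[:, i]) for i in range(nu))
            sig_e_new = omega_xi + omega_eta + AKH @ sig_e @ A.T + sdn
            sig_x_new = (
                omega_eta
                + K[t] @ H @ sig_e @ A.T
                + ABL @ sig_x @ ABL.T
                + ABL @ sig_xe @ H.T @ K[t].T
                + K[t] @ H @ sig_xe.T @ ABL.T
            )
            sig_xe = ABL @ sig_xe @ AKH.T - omega_eta
            sig_e, sig_x = sig_e_new, sig_x_new
        return K

    # initialize the filter ignoring control-dependent noise terms
    K = forward(np.zeros((T, nu, S)))
    L = np.zeros((T, nu, S))
    expected = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        L_new, _, _, expected = backward(K)
        K_new = forward(L_new)
        delta = max(np.max(np.abs(L_new - L)), np.max(np.abs(K_new - K)))
        L, K = L_new, K_new
        if delta < tol:
            converged = True
            break
    return ControlSolution(L=L, K=K, iterations=iterations, converged=converged, expected_cost=expected)


def simulate_vpsoc(
    solution: ControlSolution,
    matrices: PlantMatrices,
    geometry: SequenceGeometry,
    params: PlantParams,
    n_trials: int = 1,
    seed: int | None = None,
    noise_on: bool = True,
    eta_sd: float = 0.0,
    tag: str = "vpsoc",
) -> list[Trajectory]:
    """Run the closed loop ``u_t = -L_t xhat_t`` and return fingertip paths.

    All trials are propagated together (vectorized over the trial axis); with
    ``noise_on`` False the run is deterministic and the estimator tracks the
    true state exactly.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if noise_on and seed is None:
        raise ValueError("a seed is required for stochastic simulation")
    rng = np.random.default_rng(seed)
    A, B, C, H = matrices.A, matrices.B, matrices.C, matrices.H
    T = solution.T
    x0 = matrices.initial_state(geometry.start_arr)
    x = np.tile(x0, (n_trials, 1))
    xhat = x.copy()
    obs_sd = np.sqrt(np.diag(params.obs_covariance()))
    add_sd = np.sqrt(params.add_noise)
    from .plant import IDX_G

    g_idx = [d * N_BLOCK + IDX_G for d in range(params.n_dims)]

    pos = np.empty((n_trials, T + 1, 2))
    pos[:, 0] = matrices.positions(x)
    for t in range(T):
        u = -(xhat @ solution.L[t].T)
        y = x @ H.T
        if noise_on:
            y = y + obs_sd * rng.standard_normal(y.shape)
        innov = y - xhat @ H.T
        xhat = xhat @ A.T + u @ B.T + innov @ solution.K[t].T
        if noise_on and eta_sd > 0:
            xhat = xhat + eta_sd * rng.standard_normal(xhat.shape)
        x = x @ A.T + u @ B.T
        if noise_on:
            eps = rng.standard_normal(u.shape)
            x = x + (u * eps) @ C.T
            if add_sd > 0:
                x[:, g_idx] += add_sd * rng.standard_normal((n_trials, len(g_idx)))
        pos[:, t + 1] = matrices.positions(x)

    times = np.arange(T + 1) * params.delta
    return [
        Trajectory(
            times=times,
            positions=pos[i],
            trial=i,
            sequence_id=geometry.sequence_id,
            tag=tag,
        )
        for i in range(n_trials)
    ]


def plan_sequence(
    geometry: SequenceGeometry,
    params: PlantParams,
    h: tuple[float, ...] | None = None,
    r: float = 1e-5,
    duration_per_target: float = DEFAULT_DURATION_PER_TARGET,
    tol: float = 1e-8,
    max_iter: int = 50,
    **cost_kwargs,
) -> tuple[PlantMatrices, ViaPointCost, ControlSolution]:
    """Convenience wrapper: build plant + cost and solve the gains."""
    matrices = build_bias_plant(params)
    cost = build_cost(
        geometry, params, duration_per_target=duration_per_target, h=h, r=r, **cost_kwargs
    )
    solution = solve_lqg(
        matrices,
        cost,
        params,
        tol=tol,
        max_iter=max_iter,
        x0=matrices.initial_state(geometry.start_arr),
    )
    return matrices, cost, solution
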