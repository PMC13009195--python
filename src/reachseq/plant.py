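"""Discrete-time linear arm plant with signal-dependent motor noise.

The hand is modeled per spatial dimension as a chain of five states
``[p, pdot, f, g, xi]``: position (mm), speed (mm/s), force output of a
low-pass muscle filter, the control filter feeding it, and a constant
target/bias state ``xi``.  The control signal ``u`` enters ``g`` through a
first-order filter with time constant ``tau1``; ``g`` drives ``f`` through a
second filter (``tau2``); ``f/m`` accelerates the hand.  Motor noise is
signal-dependent: each control channel is perturbed multiplicatively with
scale ``sigma_c`` (``C = sigma_c * B``).  Only position, speed and force are
observable, with sensory noise scaled by ``sigma_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlantParams",
    "PlantMatrices",
    "PlantState",
    "N_BLOCK",
    "build_plant",
    "step_dynamics",
    "observe",
]

#: states per spatial dimension: p, pdot, f, g, xi
N_BLOCK = 5

# indices within a per-dimension block
IDX_P, IDX_V, IDX_F, IDX_G, IDX_XI = range(N_BLOCK)


@dataclass(frozen=True)
class PlantParams:
    """Physical and noise parameters of the arm plant.

    Defaults are the canonical simulation values: ``delta`` 0.01 s matches the
    100 Hz motion-capture rate; the two filter time constants are 40 ms; the
    effective hand mass is 1; signal-dependent noise scale 0.3; sensory noise
    scale 0.5 multiplying the per-channel observation variances
    ``[0.02, 0.2, 1]``; additive dynamics noise variance ``add_noise``
    (0, 8000 or 10000) enters the control-filter state only.
    """

    delta: float = 0.01
    tau1: float = 0.04
    tau2: float = 0.04
    m: float = 1.0
    sigma_c: float = 0.3
    sigma_s: float = 0.5
    obs_noise_diag: tuple[float, float, float] = (0.02, 0.2, 1.0)
    add_noise: float = 0.0
    n_dims: int = 2

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("delta, tau1 and tau2 must be positive")
        if self.m <= 0:
            raise ValueError("mass must be positive")
        if self.sigma_c < 0 or self.sigma_s < 0 or self.add_noise < 0:
            raise ValueError("noise scales must be non-negative")
        if any(v < 0 for v in self.obs_noise_diag):
            raise ValueError("obs_noise_diag must be elementwise non-negative")
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")

    @property
    def n_states(self) -> int:
        return N_BLOCK * self.n_dims

    def obs_covariance(self) -> np.ndarray:
        """Observation-noise covariance, ``sigma_s``-scaled, over all dims."""
        diag = self.sigma_s * np.asarray(self.obs_noise_diag, dtype=float)
        return np.diag(np.tile(diag, self.n_dims))

    def dynamics_covariance(self) -> np.ndarray:
        """Additive dynamics-noise covariance (g block only)."""
        cov = np.zeros((self.n_states, self.n_states))
        for d in range(self.n_dims):
            i = d * N_BLOCK + IDX_G
            cov[i, i] = self.add_noise
        return cov


@dataclass(frozen=True)
class PlantMatrices:
    """State-space matrices, block-diagonal across spatial dimensions."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    H: np.ndarray
    target: np.ndarray
    n_dims: int

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def initial_state(self, position: np.ndarray | None = None) -> np.ndarray:
        """State at rest at ``position`` with the target block set."""
        x = np.zeros(self.n_states)
        pos = np.zeros(self.n_dims) if position is None else np.asarray(position, float)
        for d in range(self.n_dims):
            x[d * N_BLOCK + IDX_P] = pos[d]
            x[d * N_BLOCK + IDX_XI] = self.target[d]
        return x

    def positions(self, x: np.ndarray) -> np.ndarray:
        """Extract hand position(s) from state vector(s) (last axis)."""
        return np.asarray(x)[..., IDX_P::N_BLOCK][..., : self.n_dims]


@dataclass
class PlantState:
    x: np.ndarray
    t: int = 0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.t < 0:
            raise ValueError("time index must be non-negative")


def _block_A(params: PlantParams) -> np.ndarray:
    d, t1, t2, m = params.delta, params.tau1, params.tau2, params.m
    return np.array(
        [
            [1.0, d, 0.0, 0.0, 0.0],
            [0.0, 1.0, d / m, 0.0, 0.0],
            [0.0, 0.0, 1.0 - d / t2, d / t2, 0.0],
            [0.0, 0.0, 0.0, 1.0 - d / t1, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ]
    )


def build_plant(params: PlantParams, target: np.ndarray | None = None) -> PlantMatrices:
    """Assemble the discrete-time plant for ``params.n_dims`` dimensions.

    ``target`` fills the constant ``xi`` block of initial states; costs that
    reference a target center read it from there.
    """
    n = params.n_dims
    if target is None:
        target = np.zeros(n)
    target = np.asarray(target, dtype=float)
    if target.shape != (n,):
        raise ValueError(f"target must have shape ({n},)")

    A = np.kron(np.eye(n), _block_A(params))
    B = np.zeros((N_BLOCK * n, n))
    for d in range(n):
        B[d * N_BLOCK + IDX_G, d] = params.delta / params.tau1
    C = params.sigma_c * B
    H = np.zeros((3 * n, N_BLOCK * n))
    for d in range(n):
        for j, idx in enumerate((IDX_P, IDX_V, IDX_F)):
            H[d * 3 + j, d * N_BLOCK + idx] = 1.0
    return PlantMatrices(A=A, B=B, C=C, H=H, target=target, n_dims=n)


def step_dynamics(
    state: PlantState,
    u: np.ndarray,
    matrices: PlantMatrices,
    params: PlantParams,
    noise_on: bool = True,
) -> PlantState:
    """Advance the plant one time step.

    ``x' = A x + B u (+ C u eps + additive g-block noise)``, with ``eps`` a
    standard normal draw per control channel when ``noise_on``.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (params.n_dims,):
        raise ValueError(f"control must have shape ({params.n_dims},)")
    x_next = matrices.A @ state.x + matrices.B @ u
    if noise_on:
        eps = state.rng.standard_normal(params.n_dims)
        x_next += matrices.C @ (u * eps)
        if params.add_noise > 0:
            sd = np.sqrt(params.add_noise)
            for d in range(params.n_dims):
                i = d * N_BLOCK + IDX_G
                x_next[i] += sd * state.rng.standard_normal()
    return PlantState(x=x_next, t=state.t + 1, rng=state.rng)


def observe(
    state: PlantState,
    params: PlantParams,
    matrices: PlantMatrices,
    noise_on: bool = True,
) -> np.ndarray:
    """Observation ``y = H x + eps_obs`` of position, speed and force."""
    y = matrices.H @ state.x
    if noise_on:
        sd = np.sqrt(np.diag(params.obs_covariance()))
        y = y + sd * state.rng.standard_normal(y.shape)
    return y
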