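"""Virtual-rat exploration: correlated random walk on a periodic square arena.

The heading diffuses as a Wiener process scaled by ``sigma_theta`` while the
position advances at the running speed, either constant or sampled from a
mean-reverting Ornstein-Uhlenbeck process (reflected at zero so the speed
stays physical).  Positions live on the torus [0, L)^2; all distances use the
minimal-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "WalkParams",
    "SpeedProcessParams",
    "Trajectory",
    "simulate_walk",
    "occupancy_map",
    "minimal_image",
]


@dataclass(frozen=True)
class WalkParams:
    """Random-walk parameters.

    v : running speed, m/s (long-term mean when a speed process is attached).
    sigma_theta : heading diffusion coefficient, rad * s^-1/2.
    dt : walk update step, seconds (10 ms default).
    arena_l : arena side length L, metres.
    """

    v: float = 0.25
    sigma_theta: float = 0.7
    dt: float = 0.01
    arena_l: float = 1.0

    def __post_init__(self):
        if self.v < 0:
            raise ValueError("require v >= 0")
        if self.dt <= 0 or self.arena_l <= 0:
            raise ValueError("require dt > 0 and arena_l > 0")


@dataclass(frozen=True)
class SpeedProcessParams:
    """Ornstein-Uhlenbeck speed modulation.

    dv = theta_v (v_bar - v) dt + sigma_v dW, reflected at v=0.
    Stationary std is approximately sigma_v / sqrt(2 theta_v).
    """

    v_bar: float = 0.25
    sigma_v: float = 0.1
    theta_v: float = 10.0

    def __post_init__(self):
        if self.theta_v <= 0 or self.sigma_v < 0:
            raise ValueError("require theta_v > 0 and sigma_v >= 0")


@dataclass
class Trajectory:
    """Sampled trajectory on the torus [0, L)^2."""

    times: np.ndarray
    positions: np.ndarray  # (n, 2), wrapped into [0, L)
    headings: np.ndarray  # (n,), radians
    speeds: np.ndarray  # (n,), m/s
    arena_l: float

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_array(self) -> np.ndarray:
        """Columns (t, x, y, heading, speed), e.g. for CSV export."""
        return np.column_stack(
            [self.times, self.positions, self.headings, self.speeds]
        )


def minimal_image(delta, arena_l: float):
    """Wrap displacement vectors into (-L/2, L/2] (minimal-image convention)."""
    return (np.asarray(delta) + 0.5 * arena_l) % arena_l - 0.5 * arena_l


def _ou_speeds(
    proc: SpeedProcessParams, n: int, dt: float, v0: float, rng: np.random.Generator
) -> np.ndarray:
    """Euler-Maruyama OU sample path of length n, reflected at zero.

    The linear recursion is evaluated vectorially (AR(1) filter); the
    reflection is re-applied sequentially only if the linear path goes
    negative, which for the default parameters is a ~10-sigma event.
    """
    phi = 1.0 - proc.theta_v * dt
    if not (0.0 < phi < 1.0):
        raise ValueError("OU speed process unstable: require theta_v * dt < 1")
    noise = proc.sigma_v * np.sqrt(dt) * rng.standard_normal(n - 1)
    drive = np.concatenate([[v0 - proc.v_bar], noise])
    dev = lfilter([1.0], [1.0, -phi], drive)
    v = proc.v_bar + dev
    if np.any(v < 0):  # redo sequentially with reflection from first crossing
        start = int(np.argmax(v < 0))
        for i in range(max(start - 1, 0), n - 1):
            vi = v[i] + proc.theta_v * (proc.v_bar - v[i]) * dt + noise[i]
            v[i + 1] = abs(vi)
    return v


def simulate_walk(
    params: WalkParams,
    duration: float,
    speed_process: SpeedProcessParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Simulate the correlated random walk for ``duration`` seconds.

    Heading increments are Normal(0, sigma_theta^2 dt); each step advances
    the position by speed*dt along the current heading before wrapping, so
    the per-step minimal-image displacement equals speed*dt exactly.
    """
    if duration < params.dt:
        raise ValueError("duration must cover at least one walk step")
    rng = np.random.default_rng(rng)
    n_steps = int(round(duration / params.dt))
    n = n_steps + 1
    dt, L = params.dt, params.arena_l

    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    if params.sigma_theta > 0:
        dtheta = params.sigma_theta * np.sqrt(dt) * rng.standard_normal(n_steps)
    else:
        dtheta = np.zeros(n_steps)
    headings = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])

    if speed_process is None:
        speeds = np.full(n, params.v)
    else:
        speeds = _ou_speeds(speed_process, n, dt, params.v, rng)

    step_len = speeds[:-1] * dt
    steps = step_len[:, None] * np.column_stack(
        [np.cos(headings[:-1]), np.sin(headings[:-1])]
    )
    start = rng.uniform(0.0, L, size=2)
    positions = (start + np.concatenate([[(0.0, 0.0)], np.cumsum(steps, axis=0)])) % L

    times = np.arange(n) * dt
    return Trajectory(times, positions, headings, speeds, L)


def occupancy_map(traj: Trajectory, n_bins: int) -> np.ndarray:
    """Normalized occupancy histogram on an n_bins x n_bins grid (sums to 1).

    Row index = y, column index = x, origin at the lower-left, matching the
    rate-map convention.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    L = traj.arena_l
    hist, _, _ = np.histogram2d(
        traj.positions[:, 1],
        traj.positions[:, 0],
        bins=n_bins,
        range=[[0, L], [0, L]],
    )
    return hist / hist.sum()
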