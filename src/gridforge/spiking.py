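"""Stochastic spiking simulator with online STDP.

Input spike trains are inhomogeneous Poisson processes whose rates follow
the spatial tuning curves along the virtual rat's trajectory.  The output
rate is a baseline plus the weighted, adaptation-filtered input spike
history (rectified at zero before the output Poisson draw).  Plasticity is
the symmetric exponential STDP window plus a per-presynaptic-spike local
normalization term, with hard non-negativity bounds on the weights.

Implementation notes
--------------------
* The adaptation integral is realized as one exact exponential trace per
  kernel component (no convolution buffer); the all-to-all spike pairing of
  the exponential STDP window is realized with per-synapse pre-traces and a
  global post-trace, which is exact for this window shape.
* At most one input spike per synapse per step (Bernoulli approximation to
  Poisson, error O((r dt)^2)); output spikes are drawn as a Poisson count.
* Same-step (dt=0) pairings are counted once, in the output-spike branch,
  where the pre-trace already includes the current step's input spikes.
* Update order within a step: Hebbian pairing terms, then the normalization
  term (evaluated at the post-Hebbian weight), then the clamp at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inputs import InputEnsemble, rates_at_positions
from .kernels import AdaptationKernel
from .trajectory import Trajectory

__all__ = [
    "PlasticityParams",
    "NeuronParams",
    "SimState",
    "WeightHistory",
    "stdp_window",
    "step",
    "run_simulation",
    "run_with_rates",
]


@dataclass(frozen=True)
class PlasticityParams:
    """STDP rule parameters.

    eta : learning rate (dimensionless, << 1).
    tau_w : decay time constant of the learning window W, seconds.
    w_tot : integral of W over all time lags, seconds.
    alpha : multiplicative weight-normalization constant (> 0).
    beta : additive weight-normalization constant.
    """

    eta: float = 2e-5
    tau_w: float = 0.05
    w_tot: float = 1.0
    alpha: float = 3.56
    beta: float = -8.78

    def __post_init__(self):
        if self.eta <= 0 or self.tau_w <= 0 or self.alpha <= 0:
            raise ValueError("require eta > 0, tau_w > 0, alpha > 0")


@dataclass(frozen=True)
class NeuronParams:
    """Output-neuron parameters: baseline rate r_0 and integration step."""

    r_0: float = 10.0
    dt: float = 1e-3

    def __post_init__(self):
        if self.r_0 < 0 or self.dt <= 0:
            raise ValueError("require r_0 >= 0 and dt > 0")


def stdp_window(plasticity: PlasticityParams, dt) -> float | np.ndarray:
    """Symmetric STDP window W(dt) = W_tot/(2 tau_w) exp(-|dt|/tau_w)."""
    dt = np.asarray(dt, dtype=float)
    out = (
        plasticity.w_tot
        / (2.0 * plasticity.tau_w)
        * np.exp(-np.abs(dt) / plasticity.tau_w)
    )
    return out if out.ndim else float(out)


@dataclass
class SimState:
    """Evolving synaptic state: weights, kernel traces, STDP traces, clock."""

    weights: np.ndarray  # (N,)
    kernel_traces: np.ndarray  # (n_components, N)
    pre_trace: np.ndarray  # (N,)
    post_trace: float
    t: float = 0.0

    @classmethod
    def initial(cls, weights: np.ndarray, kernel: AdaptationKernel) -> "SimState":
        w = np.asarray(weights, dtype=float).copy()
        if np.any(w < 0):
            raise ValueError("initial weights must be non-negative")
        return cls(
            weights=w,
            kernel_traces=np.zeros((len(kernel.components), len(w))),
            pre_trace=np.zeros(len(w)),
            post_trace=0.0,
        )


@dataclass
class WeightHistory:
    """Weight snapshots at checkpoint times, plus optional spike logs."""

    times: np.ndarray  # (n_checkpoints,)
    weights: np.ndarray  # (n_checkpoints, N)
    final_state: SimState
    output_spike_count: int = 0
    input_spike_count: int = 0
    spike_log: np.ndarray | None = None  # rows (t, channel); channel -1 = output


class _StepConstants:
    """Per-step constants precomputed once per run."""

    def __init__(self, kernel, neuron: NeuronParams, plasticity: PlasticityParams):
        comps = kernel.components
        dt = neuron.dt
        self.dt = dt
        self.r_0 = neuron.r_0
        self.amps = np.array([a for a, _ in comps])
        self.kernel_decay = np.array([np.exp(-dt / th) for _, th in comps])[:, None]
        # a spike lands uniformly within the step, so at the end-of-step rate
        # evaluation its average age is dt/2; registering it with weight
        # exp(-dt/2 theta) removes an O(dt) bias in the effective kernel
        # integral (which is a near-cancellation of the two lobes)
        self.kernel_incr = np.array([np.exp(-0.5 * dt / th) for _, th in comps])
        self.w_decay = float(np.exp(-dt / plasticity.tau_w))
        self.w0 = plasticity.w_tot / (2.0 * plasticity.tau_w)  # W(0)
        self.eta = plasticity.eta
        self.alpha = plasticity.alpha
        self.beta = plasticity.beta


def _step(state: SimState, rates: np.ndarray, c: _StepConstants,
          rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Advance one integration step in place; returns (input spikes, n_out)."""
    dt = c.dt
    spikes = rng.random(len(state.weights)) < rates * dt

    # decay all exponential traces, then register the new input spikes
    state.kernel_traces *= c.kernel_decay
    state.pre_trace *= c.w_decay
    state.post_trace *= c.w_decay

    hebb = np.zeros_like(state.weights)
    if spikes.any():
        state.kernel_traces[:, spikes] += c.kernel_incr[:, None]
        # pairing of the new input spikes with *past* output spikes
        hebb[spikes] += c.w0 * state.post_trace
        state.pre_trace[spikes] += 1.0

    r_out = c.r_0 + state.weights @ (c.amps @ state.kernel_traces)
    n_out = int(rng.poisson(max(r_out, 0.0) * dt))
    if n_out:
        # pairing of the new output spikes with past + same-step input spikes
        hebb += c.w0 * state.pre_trace * n_out
        state.post_trace += n_out

    state.weights += c.eta * hebb
    if spikes.any():
        state.weights[spikes] += c.eta * (c.beta - c.alpha * state.weights[spikes])
    np.maximum(state.weights, 0.0, out=state.weights)
    state.t += dt
    return spikes, n_out


def step(
    state: SimState,
    rates: np.ndarray,
    kernel: AdaptationKernel,
    neuron: NeuronParams,
    plasticity: PlasticityParams,
    rng: np.random.Generator,
) -> SimState:
    """Advance the simulation by one step of ``neuron.dt`` (in place)."""
    rates = np.asarray(rates, dtype=float)
    if np.max(rates, initial=0.0) * neuron.dt > 0.2:
        warnings.warn("rate * dt > 0.2: Bernoulli spike approximation is coarse")
    _step(state, rates, _StepConstants(kernel, neuron, plasticity), rng)
    return state


def run_with_rates(
    rates: np.ndarray,
    kernel: AdaptationKernel,
    neuron: NeuronParams,
    plasticity: PlasticityParams,
    w_init: np.ndarray,
    rng: np.random.Generator | int | None = None,
    checkpoints: np.ndarray | None = None,
    record_spikes: bool = False,
) -> WeightHistory:
    """Drive the simulator with an explicit (n_steps, N) input-rate array."""
    rng = np.random.default_rng(rng)
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    n_steps, n_syn = rates.shape
    state = SimState.initial(w_init, kernel)
    if len(state.weights) != n_syn:
        raise ValueError("w_init length does not match the number of inputs")
    consts = _StepConstants(kernel, neuron, plasticity)
    dt = neuron.dt
    duration = n_steps * dt
    if checkpoints is None:
        checkpoints = np.array([duration])
    ck = np.asarray(checkpoints, dtype=float)
    ck_steps = np.minimum(np.round(ck / dt).astype(int), n_steps)

    snaps = np.empty((len(ck), n_syn))
    n_in = n_out_total = 0
    log: list[tuple[float, int]] = []
    next_ck = 0
    for i in range(n_steps):
        while next_ck < len(ck) and ck_steps[next_ck] == i:
            snaps[next_ck] = state.weights
            next_ck += 1
        spikes, n_out = _step(state, rates[i], consts, rng)
        n_in += int(spikes.sum())
        n_out_total += n_out
        if record_spikes:
            t = state.t
            log.extend((t, int(j)) for j in np.flatnonzero(spikes))
            log.extend((t, -1) for _ in range(n_out))
    while next_ck < len(ck):
        snaps[next_ck] = state.weights
        next_ck += 1
    return WeightHistory(
        times=ck,
        weights=snaps,
        final_state=state,
        output_spike_count=n_out_total,
        input_spike_count=n_in,
        spike_log=np.array(log) if record_spikes else None,
    )


def run_simulation(
    ensemble: InputEnsemble,
    traj: Trajectory,
    kernel: AdaptationKernel,
    neuron: NeuronParams,
    plasticity: PlasticityParams,
    w_init: np.ndarray,
    checkpoints: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    record_spikes: bool = False,
) -> WeightHistory:
    """Simulate spiking + STDP along a trajectory.

    The trajectory (walk step, typically 10 ms) is resampled with a
    zero-order hold onto the neural integration grid (typically 1 ms).
    """
    if len(np.asarray(w_init)) != ensemble.N:
        raise ValueError("w_init length does not match ensemble size")
    rng = np.random.default_rng(rng)
    hold = max(int(round(traj.dt / neuron.dt)), 1)
    walk_rates = rates_at_positions(ensemble, traj.positions[:-1])
    rates = np.repeat(walk_rates, hold, axis=0)
    if np.max(rates, initial=0.0) * neuron.dt > 0.2:
        warnings.warn("rate * dt > 0.2: Bernoulli spike approximation is coarse")
    return run_with_rates(
        rates,
        kernel,
        neuron,
        plasticity,
        w_init,
        rng=rng,
        checkpoints=checkpoints,
        record_spikes=record_spikes,
    )
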