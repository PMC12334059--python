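"""All-to-all laterally connected excitatory Izhikevich network.

Each of the n neurons receives one-to-one external spiking input (one
input channel per neuron, weight ``S_ext``) plus lateral input equal to
the sum of incoming weights from neurons that spiked on the previous
step.  Membrane dynamics follow the two-variable Izhikevich model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I + eps
    du/dt = a (b v - u)

with a spike registered when v reaches 30 mV, after which v <- c and
u <- u + d.  The input current enters depolarizing (+I): the network is
purely excitatory and purely input-driven.  ``eps`` is fresh uniform
voltage noise in [-S_eps/2, +S_eps/2] every step.

Integration is forward Euler at dt = 1 ms with synchronous update: all
spike flags of a step are determined from the post-update voltages, and
a spike influences lateral currents only from the next step on.  State
(v, u, weights, activity traces) persists across stimulus presentations
unless explicitly reset — the network operates continuously.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from spikefam.dataset import InputSpikeTrain
from spikefam.plasticity import (
    PlasticityParams,
    anti_hebbian_update,
    hebbian_update,
    initialize_weights,
    normalize_incoming,
    update_traces,
)

__all__ = [
    "NeuronParams",
    "NetworkState",
    "SpikeRecord",
    "izhikevich_step",
    "draw_noise",
    "total_input",
    "new_network",
    "simulate_presentation",
    "write_spike_records",
]


@dataclass(frozen=True)
class NeuronParams:
    """Fixed Izhikevich neuron parameters (regular-spiking defaults).

    ``v_peak`` is the spike threshold/peak (30 mV).  ``S_eps`` scales the
    per-step uniform voltage noise; ``S_ext`` is the common feedforward
    input weight shared by all one-to-one external connections.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0
    S_eps: float = 0.6
    S_ext: float = 20.0


@dataclass
class NetworkState:
    """Mutable simulation state carried across presentations.

    ``w[i, j]`` is the incoming lateral weight to neuron i from neuron j
    (diagonal fixed at zero).  ``A`` holds the plasticity activity
    traces; ``last_spiked`` flags spikes of the previous step (one-step
    lateral delay).
    """

    v: np.ndarray
    u: np.ndarray
    w: np.ndarray
    A: np.ndarray
    last_spiked: np.ndarray
    t: float = 0.0
    steps_since_norm: int = 0

    @property
    def n(self) -> int:
        return self.v.size

    def reset_dynamics(self, params: NeuronParams = NeuronParams()) -> None:
        """Reset v, u, traces and spike flags to rest; weights persist."""
        self.v[:] = -70.0
        self.u[:] = params.b * self.v
        self.A[:] = 0.0
        self.last_spiked[:] = False


@dataclass
class SpikeRecord:
    """Per-neuron spike times (ms, multiples of dt) for one presentation window."""

    spike_times: list[np.ndarray]
    stimulated_set: np.ndarray
    duration: float

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.spike_times])


def new_network(
    n: int,
    W_total: float,
    rng: np.random.Generator,
    params: NeuronParams = NeuronParams(),
) -> NetworkState:
    """Fresh network at rest with randomly initialized normalized weights."""
    v = np.full(n, -70.0)
    return NetworkState(
        v=v,
        u=params.b * v,
        w=initialize_weights(n, W_total, rng),
        A=np.zeros(n),
        last_spiked=np.zeros(n, dtype=bool),
    )


def draw_noise(n: int, S_eps: float, rng: np.random.Generator) -> np.ndarray:
    """Per-neuron uniform voltage noise in [-S_eps/2, +S_eps/2], fresh every step."""
    if S_eps < 0:
        raise ValueError("S_eps must be non-negative")
    return (rng.random(n) - 0.5) * S_eps


def total_input(
    ext_events: np.ndarray,
    last_spiked: np.ndarray,
    w: np.ndarray,
    S_ext: float,
) -> np.ndarray:
    """I[i] = S_ext·[external event at i] + Σ_j w[i,j]·[j spiked last step]."""
    I = np.where(ext_events, S_ext, 0.0)
    if last_spiked.any():
        I = I + w @ last_spiked.astype(float)
    return I


def izhikevich_step(
    state: NetworkState,
    I: np.ndarray,
    params: NeuronParams = NeuronParams(),
    noise: np.ndarray | float = 0.0,
    dt: float = 1.0,
) -> np.ndarray:
    """One forward-Euler step of all neurons; returns the spike flags.

    Voltages reaching ``v_peak`` after the update are flagged as spikes
    and reset (v <- c, u <- u + d).  Synchronous: resets are applied
    after the whole population has been updated.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, u = state.v, state.u
    with np.errstate(over="ignore", invalid="ignore"):
        v += dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I + noise)
        u += dt * params.a * (params.b * v - u)
    if not np.isfinite(v).all():
        raise FloatingPointError("numerical blow-up")
    spiked = v >= params.v_peak
    if spiked.any():
        v[spiked] = params.c
        u[spiked] += params.d
    state.t += dt
    return spiked


def simulate_presentation(
    state: NetworkState,
    stimulus: InputSpikeTrain,
    T: float | None = None,
    plasticity: PlasticityParams | None = None,
    rng: np.random.Generator | None = None,
    params: NeuronParams = NeuronParams(),
    dt: float = 1.0,
) -> SpikeRecord:
    """Simulate one stimulus presentation; state is updated in place.

    Per step: (1) total input from this step's external events and the
    previous step's spikes; (2) Euler update with fresh noise; (3)
    plasticity update for this step's spikers, using the traces as they
    stood before this step's decay/increment; (4) trace decay and
    increment; (5) incoming-weight normalization whenever the interval
    counter fires.  With ``plasticity=None`` weights and traces are
    frozen.  Weights, traces and membrane state persist after return.
    """
    if rng is None:
        rng = np.random.default_rng()
    if T is None:
        T = stimulus.duration
    n_steps = int(round(T / dt))
    if abs(n_steps * dt - T) > 1e-9:
        raise ValueError("T must be a multiple of dt")
    events = stimulus.step_events(dt)[:n_steps]
    n = state.n
    # one uniform block per presentation; rows are consumed step by step,
    # equivalent to a fresh per-step draw
    noise_block = (rng.random((n_steps, n)) - 0.5) * params.S_eps
    spike_steps: list[tuple[float, np.ndarray]] = []
    for k in range(n_steps):
        I = total_input(events[k], state.last_spiked, state.w, params.S_ext)
        spiked = izhikevich_step(state, I, params, noise_block[k], dt)
        if plasticity is not None:
            if plasticity.eta != 0.0 and spiked.any():
                if plasticity.rule == "hebbian":
                    hebbian_update(state.w, spiked, state.A, plasticity.eta)
                else:
                    anti_hebbian_update(
                        state.w, spiked, state.A, plasticity.eta, plasticity.w_min
                    )
            state.A = update_traces(state.A, spiked, plasticity.tau_a, plasticity.a_inc, dt)
            state.steps_since_norm += 1
            if state.steps_since_norm >= plasticity.norm_interval:
                normalize_incoming(state.w, plasticity.W_total)
                state.steps_since_norm = 0
        if spiked.any():
            spike_steps.append((k * dt, np.flatnonzero(spiked)))
        state.last_spiked = spiked
    spike_lists: list[list[float]] = [[] for _ in range(n)]
    for tk, idx in spike_steps:
        for i in idx:
            spike_lists[i].append(tk)
    stimulated = np.flatnonzero([t.size > 0 for t in stimulus.times])
    return SpikeRecord(
        spike_times=[np.array(s) for s in spike_lists],
        stimulated_set=stimulated,
        duration=T,
    )


def write_spike_records(records: list[SpikeRecord], path: str | Path) -> None:
    """Columnar CSV: stimulus_index, neuron_id, time_ms."""
    rows = []
    for s, rec in enumerate(records):
        for i, times in enumerate(rec.spike_times):
            for t in times:
                rows.append((s, i, t))
    pd.DataFrame(rows, columns=["stimulus_index", "neuron_id", "time_ms"]).to_csv(
        path, index=False
    )
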