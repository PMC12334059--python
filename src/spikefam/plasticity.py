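"""Continuous unsupervised plasticity on the lateral weight matrix.

Two unidirectional trace-based rules:

* Hebbian STDP — a postsynaptic spike of neuron i potentiates every
  incoming weight w[i, j] by ``eta * A[j]`` (eta > 0), where A[j] is the
  presynaptic activity trace.  Positive-only: weights never decrease.
* anti-Hebbian STDP — a postsynaptic spike depresses w[i, j]
  multiplicatively by ``eta * A[j] * w[i, j]`` (eta < 0), clipped from
  below at ``w_min`` so connectivity cannot collapse to zero.

Activity traces decay exponentially with time constant ``tau_a`` and are
incremented by ``a_inc`` on each spike.  A homeostatic normalization
rescales every neuron's incoming weights to a fixed total ``W_total``
every ``norm_interval`` simulation steps, implementing competition for
limited synaptic resources.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PlasticityParams",
    "update_traces",
    "hebbian_update",
    "anti_hebbian_update",
    "normalize_incoming",
    "initialize_weights",
    "write_weights",
    "read_weights",
]

#: names of the meta-parameters subject to genetic optimization
OPTIMIZED_FIELDS = ("eta", "tau_a", "a_inc", "W_total", "norm_interval", "w_min")


@dataclass
class PlasticityParams:
    """Meta-parameters of the plasticity process.

    eta : learning rate; > 0 for the Hebbian rule, < 0 for anti-Hebbian.
    tau_a : activity-trace memory, ms.
    a_inc : trace increment per spike (dimensionless).
    W_total : target sum of incoming lateral weights per neuron.
    norm_interval : simulation steps between normalization events.
    w_min : weight floor, used by the anti-Hebbian rule only.
    """

    rule: str = "hebbian"
    eta: float = 0.5
    tau_a: float = 60.0
    a_inc: float = 1.0
    W_total: float = 50.0
    norm_interval: int = 1000
    w_min: float = 0.0

    def __post_init__(self) -> None:
        if self.rule not in ("hebbian", "anti_hebbian"):
            raise ValueError("rule must be 'hebbian' or 'anti_hebbian'")
        if self.rule == "hebbian" and self.eta < 0:
            raise ValueError("hebbian rule requires eta >= 0")
        if self.rule == "anti_hebbian" and self.eta > 0:
            raise ValueError("anti_hebbian rule requires eta <= 0")
        if self.tau_a <= 0:
            raise ValueError("tau_a must be positive")
        if self.W_total <= 0:
            raise ValueError("W_total must be positive")
        if self.norm_interval < 1:
            raise ValueError("norm_interval must be >= 1")
        if self.w_min < 0:
            raise ValueError("w_min must be non-negative")


def update_traces(
    A: np.ndarray, spiked: np.ndarray, tau_a: float, a_inc: float, dt: float = 1.0
) -> np.ndarray:
    """Exact exponential decay of the traces, then increment for spikers.

    Under periodic firing every p ms the trace immediately after a spike
    converges to the geometric-series fixed point
    ``a_inc / (1 − exp(−p/tau_a))``.
    """
    if tau_a <= 0:
        raise ValueError("tau_a must be positive")
    A = A * np.exp(-dt / tau_a)
    A[spiked] += a_inc
    return A


def hebbian_update(w: np.ndarray, spiked: np.ndarray, A: np.ndarray, eta: float) -> np.ndarray:
    """Potentiate incoming weights of every spiked (postsynaptic) neuron."""
    if eta < 0:
        raise ValueError("hebbian update requires eta >= 0")
    if spiked.any():
        w[spiked, :] += eta * A[None, :]
        np.fill_diagonal(w, 0.0)
    return w


def anti_hebbian_update(
    w: np.ndarray, spiked: np.ndarray, A: np.ndarray, eta: float, w_min: float = 0.0
) -> np.ndarray:
    """Multiplicatively depress incoming weights of spiked neurons, floored at w_min.

    The multiplicative form keeps the depression proportional to the
    current weight, so a constantly co-active pair decays geometrically:
    after k postsynaptic spikes with constant presynaptic trace A,
    ``w = w0 * (1 + eta*A)**k`` (until the floor is reached).
    """
    if eta > 0:
        raise ValueError("anti-hebbian update requires eta <= 0")
    if w_min < 0:
        raise ValueError("w_min must be non-negative")
    if spiked.any():
        rows = w[spiked, :]
        rows += eta * A[None, :] * rows
        np.maximum(rows, w_min, out=rows)
        w[spiked, :] = rows
        np.fill_diagonal(w, 0.0)  # floor must not create self-connections
    return w


def normalize_incoming(w: np.ndarray, W_total: float) -> np.ndarray:
    """Rescale each row (incoming weights of one neuron) to sum to W_total.

    Zero rows are left unchanged.  Idempotent on already-normalized rows.
    """
    if W_total <= 0:
        raise ValueError("W_total must be positive")
    sums = w.sum(axis=1)
    active = sums > 0
    w[active, :] *= (W_total / sums[active])[:, None]
    return w


def initialize_weights(n: int, W_total: float, rng: np.random.Generator) -> np.ndarray:
    """Random non-negative all-to-all matrix with zero diagonal, rows summing to W_total."""
    if n < 2:
        raise ValueError("need at least 2 neurons")
    w = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(w, 0.0)
    return normalize_incoming(w, W_total)


def write_weights(w: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, w, delimiter=",")


def read_weights(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")
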