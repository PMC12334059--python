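"""Familiarity decoding from spike trains: spike count, Rsync, thresholding.

Both readouts are computed over the externally stimulated population
only (the network is purely input-driven, so unstimulated neurons are
silent anyway).  The spike-count readout is the mean per-neuron spike
count over the presentation window T.  Rsync measures population
synchrony as the temporal variance of the population-mean activation
trace divided by the mean per-neuron trace variance; traces come from
convolving each binary spike train with an exponential kernel
exp(-t/tau), tau = 5 ms.  Rsync = 1 for perfectly synchronous firing and
tends to 0 for large independent populations.

Classification is a simple threshold: for Hebbian networks higher
values mean familiar (repetition enhancement); for anti-Hebbian
networks lower values mean familiar (repetition suppression).  Accuracy
is balanced by the novel fraction f_new = 1/(1+p_new).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from spikefam.network import SpikeRecord

__all__ = [
    "DecoderConfig",
    "EvaluationResult",
    "population_spike_count",
    "activation_trace",
    "rsync",
    "classify",
    "balanced_accuracy",
    "best_threshold",
]


@dataclass
class DecoderConfig:
    """Threshold decoder configuration.

    ``direction`` is tied to the plasticity rule: ``above_is_familiar``
    for Hebbian networks, ``below_is_familiar`` for anti-Hebbian.
    """

    metric: str = "spike_count"
    tau_kernel: float = 5.0
    T: float = 1000.0
    threshold: float = 0.0
    direction: str = "above_is_familiar"

    def __post_init__(self) -> None:
        if self.metric not in ("spike_count", "rsync"):
            raise ValueError("metric must be 'spike_count' or 'rsync'")
        if self.tau_kernel <= 0:
            raise ValueError("tau_kernel must be positive")
        if self.direction not in ("above_is_familiar", "below_is_familiar"):
            raise ValueError("invalid direction")


@dataclass
class EvaluationResult:
    P_TP: float
    P_FP: float
    f_new: float
    balanced_accuracy: float


def population_spike_count(record: SpikeRecord, population: np.ndarray, T: float | None = None) -> float:
    """Mean spike count per neuron over ``population`` within [0, T)."""
    population = np.asarray(population)
    if population.size == 0:
        raise ValueError("empty population")
    if T is None:
        T = record.duration
    return float(
        np.mean([np.count_nonzero(record.spike_times[i] < T) for i in population])
    )


def activation_trace(
    spike_times: np.ndarray, tau_kernel: float, T: float, dt: float = 1.0
) -> np.ndarray:
    """Causal exponential-kernel trace sampled on the dt grid.

    Value at grid time t is sum over spikes t_s <= t of exp(-(t-t_s)/tau).
    """
    if tau_kernel <= 0:
        raise ValueError("tau_kernel must be positive")
    n_steps = int(round(T / dt))
    trace = np.zeros(n_steps)
    spike_times = np.asarray(spike_times)
    spike_times = spike_times[(spike_times >= 0) & (spike_times < T)]
    if spike_times.size == 0:
        return trace
    bins = np.minimum((spike_times / dt).astype(int), n_steps - 1)
    impulses = np.bincount(bins, minlength=n_steps).astype(float)
    decay = np.exp(-dt / tau_kernel)
    # first-order recursive filter: trace[k] = decay*trace[k-1] + impulses[k]
    return lfilter([1.0], [1.0, -decay], impulses)


def _trace_matrix(record: SpikeRecord, population: np.ndarray, tau: float, T: float, dt: float) -> np.ndarray:
    n_steps = int(round(T / dt))
    decay = np.exp(-dt / tau)
    imps = np.zeros((len(population), n_steps))
    for r, i in enumerate(population):
        st = record.spike_times[i]
        st = st[(st >= 0) & (st < T)]
        if st.size:
            np.add.at(imps[r], np.minimum((st / dt).astype(int), n_steps - 1), 1.0)
    return lfilter([1.0], [1.0, -decay], imps, axis=1)


def rsync(
    record: SpikeRecord,
    population: np.ndarray,
    tau_kernel: float = 5.0,
    T: float | None = None,
    dt: float = 1.0,
) -> float:
    """Population synchrony: Var_t(mean_i A_i) / mean_i(Var_t A_i) in [0, 1].

    Returns 0 when every trace is constant (no spikes in the window).
    """
    population = np.asarray(population)
    if population.size == 0:
        raise ValueError("empty population")
    if T is None:
        T = record.duration
    traces = _trace_matrix(record, population, tau_kernel, T, dt)
    denom = float(np.mean(np.var(traces, axis=1)))
    if denom == 0.0:
        return 0.0
    num = float(np.var(traces.mean(axis=0)))
    return num / denom


def classify(value: float, cfg: DecoderConfig) -> str:
    """Threshold classification; exact ties are called novel."""
    if not np.isfinite(cfg.threshold):
        raise ValueError("threshold must be finite")
    if cfg.direction == "above_is_familiar":
        return "familiar" if value > cfg.threshold else "novel"
    return "familiar" if value < cfg.threshold else "novel"


def balanced_accuracy(P_TP: float, P_FP: float, p_new: float = 0.5) -> float:
    """Acc = (1 − f_new)·P_TP + f_new·(1 − P_FP), with f_new = 1/(1+p_new).

    At p_new = 0.5 the novel fraction is 2/3, so the constant
    always-novel classifier scores 2/3.
    """
    for x in (P_TP, P_FP, p_new):
        if not 0.0 <= x <= 1.0:
            raise ValueError("inputs must lie in [0, 1]")
    f_new = 1.0 / (1.0 + p_new)
    return (1.0 - f_new) * P_TP + f_new * (1.0 - P_FP)


def _empirical_accuracy(
    values: np.ndarray, labels: np.ndarray, threshold: float, p_new: float, direction: str
) -> float:
    if direction == "above_is_familiar":
        pred = values > threshold
    else:
        pred = values < threshold
    fam = labels == 1
    P_TP = float(pred[fam].mean()) if fam.any() else 0.0
    P_FP = float(pred[~fam].mean()) if (~fam).any() else 0.0
    return balanced_accuracy(P_TP, P_FP, p_new)


def best_threshold(
    values: np.ndarray,
    labels: np.ndarray,
    p_new: float = 0.5,
    direction: str = "above_is_familiar",
) -> tuple[float, float]:
    """Exhaustive threshold scan maximizing balanced accuracy.

    Candidates are midpoints between consecutive sorted unique metric
    values plus sentinels below/above all values; ties in accuracy break
    toward the smaller threshold.  The result never scores below the
    constant classifier (a sentinel realizes it).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValueError("empty input")
    uniq = np.unique(values)
    span = max(uniq[-1] - uniq[0], 1.0)
    candidates = np.concatenate(
        ([uniq[0] - span], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + span])
    )
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = _empirical_accuracy(values, labels, t, p_new, direction)
        if acc > best_acc:
            best_t, best_acc = t, acc
    return float(best_t), float(best_acc)


def evaluate_predictions(
    values: np.ndarray, labels: np.ndarray, cfg: DecoderConfig, p_new: float = 0.5
) -> EvaluationResult:
    """Empirical P_TP, P_FP and balanced accuracy for a fixed threshold."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if cfg.direction == "above_is_familiar":
        pred = values > cfg.threshold
    else:
        pred = values < cfg.threshold
    fam = labels == 1
    P_TP = float(pred[fam].mean()) if fam.any() else 0.0
    P_FP = float(pred[~fam].mean()) if (~fam).any() else 0.0
    f_new = 1.0 / (1.0 + p_new)
    return EvaluationResult(P_TP, P_FP, f_new, balanced_accuracy(P_TP, P_FP, p_new))
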