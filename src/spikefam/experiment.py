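"""End-to-end protocol: optimize at one repeat interval, evaluate across many.

The headline question is temporal generalization: plasticity
meta-parameters are optimized for a single repeat interval R, then the
network is evaluated on fresh continual-familiarity streams with R
ranging from 1 to 30, using the threshold frozen at optimization time.
Generalizability is the mean balanced accuracy over the tested R values.

Seeding is hierarchical from one master seed (master -> replicate ->
GA / per-R dataset+network streams, via numpy SeedSequence spawning),
so a full protocol is bit-reproducible and every evaluation dataset is
disjoint from the optimization data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spikefam.connectivity import connectivity_stats
from spikefam.dataset import DatasetConfig, generate_dataset
from spikefam.decoding import DecoderConfig, evaluate_predictions
from spikefam.network import NeuronParams
from spikefam.optimize import GAConfig, Individual, metric_values, run_ga
from spikefam.plasticity import PlasticityParams

__all__ = ["SweepResult", "run_sweep", "run_replicated_protocol"]

DEFAULT_R_LIST = tuple(range(1, 31))


@dataclass
class SweepResult:
    """Balanced accuracy per repeat interval plus the mean over intervals."""

    r_values: list[int]
    accuracies: list[float]
    metadata: dict = field(default_factory=dict)

    @property
    def generalizability(self) -> float:
        acc = np.asarray(self.accuracies, dtype=float)
        return float(np.nanmean(acc))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"R": self.r_values, "balanced_accuracy": self.accuracies})
        for k, v in self.metadata.items():
            df[k] = v
        return df


def run_sweep(
    params: PlasticityParams,
    threshold: float,
    metric: str = "spike_count",
    r_list: tuple[int, ...] = DEFAULT_R_LIST,
    task_template: DatasetConfig = DatasetConfig(),
    n_stimuli: int = 500,
    rng: np.random.Generator | None = None,
    neuron_params: NeuronParams = NeuronParams(),
) -> SweepResult:
    """Evaluate a frozen parameter set + threshold across repeat intervals.

    For each R a fresh network processes a fresh ``n_stimuli``-long
    stream with plasticity on; each stimulus is classified against the
    frozen threshold and accuracy is balanced by the novel fraction.
    Per-R simulation failures are recorded as NaN.
    """
    if rng is None:
        rng = np.random.default_rng()
    direction = "above_is_familiar" if params.rule == "hebbian" else "below_is_familiar"
    dec = DecoderConfig(metric=metric, threshold=threshold, direction=direction)
    accs = []
    for R in r_list:
        cfg = DatasetConfig(
            n_stimuli=n_stimuli,
            repeat_interval=R,
            p_new=task_template.p_new,
            dim=task_template.dim,
            n_active=task_template.n_active,
        )
        ds = generate_dataset(cfg, rng)
        try:
            values = metric_values(ds, params, metric, rng, neuron_params)
        except FloatingPointError:
            accs.append(float("nan"))
            continue
        res = evaluate_predictions(values, ds.labels, dec, cfg.p_new)
        accs.append(res.balanced_accuracy)
    return SweepResult(
        r_values=list(r_list),
        accuracies=accs,
        metadata={
            "rule": params.rule,
            "metric": metric,
            "sparseness": task_template.n_active and _sparseness(task_template),
            "threshold": threshold,
        },
    )


def _sparseness(cfg: DatasetConfig) -> float:
    return abs(cfg.dim - 2 * cfg.n_active) / cfg.dim


def run_replicated_protocol(
    rules: tuple[str, ...] = ("hebbian",),
    metrics: tuple[str, ...] = ("spike_count",),
    n_active_levels: tuple[int, ...] = (5,),
    r_opt_values: tuple[int, ...] = (3,),
    n_replicates: int = 2,
    r_list: tuple[int, ...] = DEFAULT_R_LIST,
    n_stimuli: int = 500,
    ga_config: GAConfig | None = None,
    master_seed: int = 0,
    dim: int = 100,
    with_connectivity: bool = True,
) -> pd.DataFrame:
    """Replicated optimize-then-sweep grid; one row per (cell, replicate, R).

    Each grid cell (rule, metric, sparseness level, optimization R) is
    independently optimized ``n_replicates`` times; every replicate gets
    its own spawned seed stream, then a full R sweep and (optionally)
    connectivity statistics of the final learned weight matrix.
    """
    rows = []
    master = np.random.SeedSequence(master_seed)
    for rule in rules:
        for metric in metrics:
            for n_active in n_active_levels:
                for r_opt in r_opt_values:
                    for rep in range(n_replicates):
                        child = master.spawn(1)[0]
                        ga_rng = np.random.default_rng(child.spawn(1)[0])
                        sweep_rng = np.random.default_rng(child.spawn(1)[0])
                        cfg = ga_config or GAConfig()
                        cfg = GAConfig(
                            population_size=cfg.population_size,
                            n_elite=cfg.n_elite,
                            n_mutants=cfg.n_mutants,
                            n_crossover=cfg.n_crossover,
                            n_random=cfg.n_random,
                            max_generations=cfg.max_generations,
                            stagnation_limit=cfg.stagnation_limit,
                            perfect_accuracy=cfg.perfect_accuracy,
                            eval_dataset_size=cfg.eval_dataset_size,
                            param_ranges=cfg.param_ranges,
                            rule=rule,
                        )
                        task = DatasetConfig(
                            n_stimuli=cfg.eval_dataset_size,
                            repeat_interval=r_opt,
                            dim=dim,
                            n_active=n_active,
                        )
                        best, _ = run_ga(cfg, task, metric, ga_rng)
                        sweep = run_sweep(
                            best.params,
                            best.threshold,
                            metric,
                            r_list,
                            task,
                            n_stimuli,
                            sweep_rng,
                        )
                        sp = _sparseness(task)
                        stats = None
                        if with_connectivity:
                            # re-learn once more to expose the final weights
                            ds = generate_dataset(task, sweep_rng)
                            from spikefam.network import new_network
                            from spikefam.dataset import poisson_encode
                            from spikefam.network import simulate_presentation

                            state = new_network(dim, best.params.W_total, sweep_rng)
                            for pattern in ds.stimuli:
                                train = poisson_encode(pattern, rng=sweep_rng)
                                simulate_presentation(
                                    state, train, plasticity=best.params, rng=sweep_rng
                                )
                            stats = connectivity_stats(state.w, best.params.W_total)
                        for R, acc in zip(sweep.r_values, sweep.accuracies):
                            row = {
                                "rule": rule,
                                "metric": metric,
                                "sparseness": sp,
                                "R_opt": r_opt,
                                "replicate": rep,
                                "R": R,
                                "balanced_accuracy": acc,
                                "generalizability": sweep.generalizability,
                                "fitness": best.fitness,
                            }
                            if stats is not None:
                                row.update(
                                    {
                                        "gini": stats.gini,
                                        "transitivity": stats.transitivity,
                                        "betweenness_mean": stats.betweenness_mean,
                                    }
                                )
                            rows.append(row)
    return pd.DataFrame(rows)
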