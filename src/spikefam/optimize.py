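"""Genetic meta-parameter optimization of the plasticity process.

Each generation holds 12 parameter sets ("descendants").  Every set is
scored by simulating a fresh network on a continual-familiarity dataset
(N = 300 stimuli by default), fitting the best classification threshold
on the resulting per-stimulus metric values, and taking the balanced
accuracy as fitness.  The next generation is composed of:

* the 3 best-performing sets (elites, copied unmodified),
* 3 mutants — in each elite, one random parameter scaled by U(0.75, 1.25),
* 3 crossovers — from the 3 elite pairs, each child inheriting a random
  half of parameter names from one parent and the rest from the other,
* 3 freshly sampled random sets.

The loop terminates after ``max_generations`` generations, when any set
reaches fitness 1.0, or when the generation-best fitness has failed to
strictly improve for ``stagnation_limit`` consecutive generations.  The
threshold of the best-ever individual is frozen for later evaluation.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from spikefam.dataset import DatasetConfig, generate_dataset, poisson_encode
from spikefam.decoding import best_threshold, population_spike_count, rsync
from spikefam.network import NeuronParams, new_network, simulate_presentation
from spikefam.plasticity import OPTIMIZED_FIELDS, PlasticityParams

__all__ = [
    "ParamRange",
    "GAConfig",
    "Individual",
    "sample_params",
    "evaluate_individual",
    "mutate",
    "crossover",
    "run_ga",
    "write_ga_log",
]


@dataclass(frozen=True)
class ParamRange:
    """Sampling bounds for one meta-parameter."""

    low: float
    high: float
    log: bool = False
    integer: bool = False

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            x = float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        else:
            x = float(rng.uniform(self.low, self.high))
        return self.clamp(x)

    def clamp(self, x: float) -> float:
        x = min(max(x, self.low), self.high)
        if self.integer:
            x = max(int(round(x)), int(np.ceil(self.low)))
        return x


#: default sampling ranges spanning the dynamically meaningful regimes
DEFAULT_RANGES: dict[str, ParamRange] = {
    "eta": ParamRange(1e-4, 1.0, log=True),
    "tau_a": ParamRange(1.0, 500.0),
    "a_inc": ParamRange(0.1, 5.0),
    "W_total": ParamRange(1.0, 200.0),
    "norm_interval": ParamRange(1, 10_000, log=True, integer=True),
    "w_min": ParamRange(0.0, 1.0),
}


@dataclass
class GAConfig:
    population_size: int = 12
    n_elite: int = 3
    n_mutants: int = 3
    n_crossover: int = 3
    n_random: int = 3
    max_generations: int = 300
    stagnation_limit: int = 15
    perfect_accuracy: float = 1.0
    eval_dataset_size: int = 300
    param_ranges: dict[str, ParamRange] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    rule: str = "hebbian"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_elite + self.n_mutants + self.n_crossover + self.n_random != self.population_size:
            raise ValueError("group sizes must add up to population_size")


@dataclass
class Individual:
    params: PlasticityParams
    fitness: float = -1.0
    threshold: float = float("nan")

    def param_dict(self) -> dict[str, float]:
        return {name: getattr(self.params, name) for name in OPTIMIZED_FIELDS}


def _to_params(rule: str, values: dict[str, float]) -> PlasticityParams:
    vals = dict(values)
    # eta is sampled as a magnitude; the anti-Hebbian rule uses it negated
    if rule == "anti_hebbian":
        vals["eta"] = -abs(vals["eta"])
    else:
        vals["w_min"] = 0.0
    return PlasticityParams(rule=rule, **vals)


def sample_params(cfg: GAConfig, rng: np.random.Generator) -> PlasticityParams:
    values = {name: r.sample(rng) for name, r in cfg.param_ranges.items()}
    values["norm_interval"] = int(values["norm_interval"])
    return _to_params(cfg.rule, values)


def evaluate_individual(
    ind: Individual,
    task: DatasetConfig,
    metric: str = "spike_count",
    rng: np.random.Generator | None = None,
    neuron_params: NeuronParams = NeuronParams(),
) -> Individual:
    """Score one parameter set on a freshly simulated dataset.

    A fresh network processes the whole stimulus stream continuously;
    the per-stimulus metric values are thresholded at the accuracy-
    maximizing point, which becomes the individual's frozen threshold.
    A numerical blow-up during simulation yields fitness 0.
    """
    if rng is None:
        rng = np.random.default_rng()
    ds = generate_dataset(task, rng)
    direction = "above_is_familiar" if ind.params.rule == "hebbian" else "below_is_familiar"
    try:
        values = metric_values(ds, ind.params, metric, rng, neuron_params)
    except FloatingPointError:
        warnings.warn("simulation blew up; assigning fitness 0", RuntimeWarning, stacklevel=2)
        ind.fitness = 0.0
        ind.threshold = 0.0
        return ind
    thr, acc = best_threshold(values, ds.labels, task.p_new, direction)
    ind.fitness = acc
    ind.threshold = thr
    return ind


def metric_values(
    ds,
    params: PlasticityParams,
    metric: str,
    rng: np.random.Generator,
    neuron_params: NeuronParams = NeuronParams(),
    T: float = 1000.0,
) -> np.ndarray:
    """Simulate a stimulus stream and return the per-stimulus decoder metric."""
    dim = ds.stimuli[0].dim
    state = new_network(dim, params.W_total, rng, neuron_params)
    values = np.empty(len(ds))
    for t, pattern in enumerate(ds.stimuli):
        train = poisson_encode(pattern, rng=rng, duration=T)
        rec = simulate_presentation(state, train, T, params, rng, neuron_params)
        pop = rec.stimulated_set
        if metric == "spike_count":
            values[t] = population_spike_count(rec, pop)
        elif metric == "rsync":
            values[t] = rsync(rec, pop)
        else:
            raise ValueError("metric must be 'spike_count' or 'rsync'")
    return values


def mutate(ind: Individual, cfg: GAConfig, rng: np.random.Generator) -> Individual:
    """Scale exactly one uniformly chosen parameter by U(0.75, 1.25), clamped."""
    names = [n for n in cfg.param_ranges if cfg.rule == "anti_hebbian" or n != "w_min"]
    name = names[rng.integers(len(names))]
    values = {n: getattr(ind.params, n) for n in OPTIMIZED_FIELDS}
    values["eta"] = abs(values["eta"])
    values[name] = cfg.param_ranges[name].clamp(values[name] * rng.uniform(0.75, 1.25))
    values["norm_interval"] = int(values["norm_interval"])
    return Individual(_to_params(cfg.rule, values))


def crossover(p1: Individual, p2: Individual, cfg: GAConfig, rng: np.random.Generator) -> Individual:
    """Child takes a random half of parameter names from p1, the rest from p2."""
    names = sorted(cfg.param_ranges)
    n_from_p1 = (len(names) + 1) // 2  # odd counts: extra from p1
    from_p1 = set(rng.choice(names, size=n_from_p1, replace=False).tolist())
    values = {}
    for n in names:
        src = p1 if n in from_p1 else p2
        values[n] = getattr(src.params, n)
    values["eta"] = abs(values["eta"])
    values["norm_interval"] = int(values["norm_interval"])
    return Individual(_to_params(cfg.rule, values))


def run_ga(
    cfg: GAConfig,
    task: DatasetConfig,
    metric: str = "spike_count",
    rng: np.random.Generator | None = None,
    neuron_params: NeuronParams = NeuronParams(),
    evaluate_fn=None,
) -> tuple[Individual, pd.DataFrame]:
    """Run the generation loop; returns the best-ever individual and a log.

    Each generation is evaluated on a freshly generated dataset (new
    seed stream) so the fitted thresholds do not overfit a single
    stimulus sequence.  ``evaluate_fn(ind, task, metric, rng)`` may
    replace the full-simulation fitness, e.g. for cheap surrogate runs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if evaluate_fn is None:
        def evaluate_fn(ind, task, metric, rng):
            return evaluate_individual(ind, task, metric, rng, neuron_params)
    population = [Individual(sample_params(cfg, rng)) for _ in range(cfg.population_size)]
    best_ever: Individual | None = None
    prev_gen_best = -np.inf
    stagnant = 0
    history = []
    for gen in range(cfg.max_generations):
        for ind in population:
            evaluate_fn(ind, task, metric, rng)
        population.sort(key=lambda i: i.fitness, reverse=True)
        gen_best = population[0]
        if best_ever is None or gen_best.fitness > best_ever.fitness:
            best_ever = copy.deepcopy(gen_best)
        history.append(
            {
                "generation": gen,
                "best_fitness": gen_best.fitness,
                "mean_fitness": float(np.mean([i.fitness for i in population])),
                "best_params": json.dumps(gen_best.param_dict()),
            }
        )
        if gen_best.fitness >= cfg.perfect_accuracy:
            break
        if gen_best.fitness > prev_gen_best:
            stagnant = 0
        else:
            stagnant += 1
        prev_gen_best = max(prev_gen_best, gen_best.fitness)
        if stagnant >= cfg.stagnation_limit:
            break
        elites = [copy.deepcopy(population[i]) for i in range(cfg.n_elite)]
        mutants = [mutate(elites[i % cfg.n_elite], cfg, rng) for i in range(cfg.n_mutants)]
        pairs = [(0, 1), (0, 2), (1, 2)]
        children = [
            crossover(elites[a % cfg.n_elite], elites[b % cfg.n_elite], cfg, rng)
            for a, b in pairs[: cfg.n_crossover]
        ]
        randoms = [Individual(sample_params(cfg, rng)) for _ in range(cfg.n_random)]
        population = elites + mutants + children + randoms
    assert best_ever is not None
    return best_ever, pd.DataFrame(history)


def write_ga_log(history: pd.DataFrame, best: Individual, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    history.to_csv(out / "ga_log.csv", index=False)
    payload = {
        "rule": best.params.rule,
        "fitness": best.fitness,
        "threshold": best.threshold,
        **best.param_dict(),
    }
    (out / "best_params.json").write_text(json.dumps(payload, indent=2))
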