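"""Binary stimulus patterns, continual-familiarity sequences, Poisson encodings.

Stimuli are fixed-sparseness binary vectors: each pattern has exactly
``n_active`` ones out of ``dim`` positions.  A continual-familiarity
dataset is an ordered stream in which each stimulus is either novel or an
exact copy of the stimulus ``R`` steps earlier; copies are labelled
familiar (1).  Patterns are turned into spiking input by a homogeneous
Poisson process on each active channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinaryPattern",
    "DatasetConfig",
    "FamiliarityDataset",
    "CorrelationConfig",
    "InputSpikeTrain",
    "sparseness_of",
    "generate_pattern",
    "generate_dataset",
    "generate_correlated_patterns",
    "jaccard",
    "poisson_encode",
    "write_dataset",
    "read_dataset",
    "write_spike_train",
    "read_spike_train",
]


@dataclass(frozen=True)
class BinaryPattern:
    """A binary stimulus vector with a fixed number of active bits."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ValueError("pattern must be a 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("pattern entries must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    @property
    def dim(self) -> int:
        return self.bits.size

    @property
    def n_active(self) -> int:
        return int(self.bits.sum())

    @property
    def n_inactive(self) -> int:
        return self.dim - self.n_active

    @property
    def active_set(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())

    @property
    def sparseness(self) -> float:
        return sparseness_of(self.n_inactive, self.n_active)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryPattern):
            return NotImplemented
        return self.bits.shape == other.bits.shape and bool((self.bits == other.bits).all())

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())


@dataclass(frozen=True)
class DatasetConfig:
    """Parameters of a continual-familiarity stream.

    ``p_new`` is the probability that a stimulus is novel; a stimulus is a
    copy of the one ``repeat_interval`` steps earlier with probability
    ``1 − p_new`` (when an eligible source exists).  At ``p_new = 0.5``
    the expected familiar fraction is 1/3.
    """

    n_stimuli: int = 500
    repeat_interval: int = 3
    p_new: float = 0.5
    dim: int = 100
    n_active: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_stimuli <= 0:
            raise ValueError("n_stimuli must be positive")
        if not 0 < self.repeat_interval < self.n_stimuli:
            raise ValueError("repeat_interval must be in (0, n_stimuli)")
        if not 0.0 <= self.p_new <= 1.0:
            raise ValueError("p_new must lie in [0, 1]")
        if not 0 < self.n_active <= self.dim:
            raise ValueError("n_active must lie in (0, dim]")


@dataclass
class FamiliarityDataset:
    """Ordered stimuli with familiar/novel labels.

    ``labels[t] == 1`` means ``stimuli[t]`` is an exact copy of
    ``stimuli[t − R]``; ``source_index[t]`` then records ``t − R``
    (−1 for novel stimuli).  Every distinct pattern occurs at most twice.
    """

    stimuli: list[BinaryPattern]
    labels: np.ndarray
    source_index: np.ndarray
    config: DatasetConfig | None = None

    def __len__(self) -> int:
        return len(self.stimuli)

    @property
    def familiar_fraction(self) -> float:
        return float(np.mean(self.labels))


@dataclass(frozen=True)
class CorrelationConfig:
    """Template-similarity control for correlated pattern generation.

    ``p_match`` is the fraction of each pattern's active bits inherited
    from the template's active positions; the expected overlap with the
    template is ``K * p_match`` for patterns with K active bits.
    """

    p_match: float
    template: BinaryPattern

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_match <= 1.0:
            raise ValueError("p_match must lie in [0, 1]")


@dataclass
class InputSpikeTrain:
    """Per-channel Poisson spike times for one stimulus presentation.

    ``times[i]`` holds the sorted event times (ms, continuous in
    ``[0, T)``) of channel ``i``; channels whose pattern bit is 0 are
    empty.  :meth:`step_events` discretizes onto the simulation grid,
    collapsing coincident events within one ``dt`` bin to a single spike.
    """

    times: list[np.ndarray]
    rate: float
    duration: float
    dt: float = 1.0

    @property
    def n_channels(self) -> int:
        return len(self.times)

    def step_events(self, dt: float | None = None) -> np.ndarray:
        """Boolean (n_steps, n_channels) array of per-step external events."""
        dt = self.dt if dt is None else dt
        n_steps = int(round(self.duration / dt))
        events = np.zeros((n_steps, self.n_channels), dtype=bool)
        for i, t in enumerate(self.times):
            if t.size:
                events[np.minimum((t // dt).astype(int), n_steps - 1), i] = True
        return events


def sparseness_of(d0: int, d1: int) -> float:
    """Sparseness Sp = |d0 − d1| / (d0 + d1) of a binary vector.

    ``d0`` and ``d1`` are the counts of zeros and ones.  Sp = 0.6 for an
    80/20 split, 0.8 for 90/10, 0.9 for 95/5.
    """
    if d0 + d1 <= 0:
        raise ValueError("empty pattern")
    return abs(d0 - d1) / (d0 + d1)


def generate_pattern(dim: int, n_active: int, rng: np.random.Generator) -> BinaryPattern:
    """Uniform random pattern with exactly ``n_active`` ones."""
    if not 0 < n_active <= dim:
        raise ValueError("n_active must lie in (0, dim]")
    bits = np.zeros(dim, dtype=np.uint8)
    bits[rng.choice(dim, size=n_active, replace=False)] = 1
    return BinaryPattern(bits)


def generate_dataset(cfg: DatasetConfig, rng: np.random.Generator | None = None) -> FamiliarityDataset:
    """Generate a continual-familiarity stream.

    At step t the stimulus is a copy of the one at t − R with probability
    ``1 − p_new``, provided that source exists, was itself novel and has
    not been repeated yet (so no pattern appears more than twice);
    otherwise a fresh random pattern is emitted.  Fresh patterns are
    re-drawn on the rare collision with an already-emitted pattern so
    that labels stay exact.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    R = cfg.repeat_interval
    stimuli: list[BinaryPattern] = []
    labels = np.zeros(cfg.n_stimuli, dtype=np.int8)
    source = np.full(cfg.n_stimuli, -1, dtype=np.int64)
    repeated = np.zeros(cfg.n_stimuli, dtype=bool)
    seen: set[BinaryPattern] = set()
    for t in range(cfg.n_stimuli):
        src = t - R
        eligible = src >= 0 and labels[src] == 0 and not repeated[src]
        if eligible and rng.random() >= cfg.p_new:
            stimuli.append(stimuli[src])
            labels[t] = 1
            source[t] = src
            repeated[src] = True
        else:
            while True:
                pat = generate_pattern(cfg.dim, cfg.n_active, rng)
                if pat not in seen:
                    break
            stimuli.append(pat)
            seen.add(pat)
    return FamiliarityDataset(stimuli, labels, source, cfg)


def generate_correlated_patterns(
    n: int,
    dim: int,
    n_active: int,
    corr: CorrelationConfig,
    rng: np.random.Generator,
) -> list[BinaryPattern]:
    """Patterns sharing ``round(K·p_match)`` active bits with a template.

    Each pattern has exactly ``n_active`` ones: ``round(K·p_match)``
    drawn uniformly from the template's active positions and the rest
    from its inactive positions, so sparseness is constant across the
    set.  Rounding is round-half-to-even.
    """
    template = corr.template
    if template.dim != dim or template.n_active != n_active:
        raise ValueError("template sparseness mismatch")
    k_match = int(np.round(n_active * corr.p_match))
    active = np.flatnonzero(template.bits)
    inactive = np.flatnonzero(template.bits == 0)
    if n_active - k_match > inactive.size:
        raise ValueError("not enough inactive template positions")
    out = []
    for _ in range(n):
        bits = np.zeros(dim, dtype=np.uint8)
        bits[rng.choice(active, size=k_match, replace=False)] = 1
        bits[rng.choice(inactive, size=n_active - k_match, replace=False)] = 1
        out.append(BinaryPattern(bits))
    return out


def jaccard(a: BinaryPattern, b: BinaryPattern) -> float:
    """Jaccard similarity |A∩B| / |A∪B| of the active-bit sets."""
    if a.dim != b.dim:
        raise ValueError("dimension mismatch")
    inter = int(np.sum((a.bits == 1) & (b.bits == 1)))
    union = int(np.sum((a.bits == 1) | (b.bits == 1)))
    return 1.0 if union == 0 else inter / union


def mean_pairwise_jaccard(patterns: list[BinaryPattern]) -> float:
    """Average Jaccard similarity over all unordered pattern pairs."""
    mat = np.stack([p.bits for p in patterns]).astype(np.int32)
    inter = mat @ mat.T
    sizes = mat.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    iu = np.triu_indices(len(patterns), k=1)
    with np.errstate(invalid="ignore"):
        vals = np.where(union[iu] > 0, inter[iu] / union[iu], 1.0)
    return float(vals.mean())


def poisson_encode(
    pattern: BinaryPattern,
    rate: float = 100.0,
    duration: float = 1000.0,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> InputSpikeTrain:
    """Encode a pattern as homogeneous Poisson spike trains.

    Each active channel fires as a Poisson process at ``rate`` Hz over
    ``duration`` ms (event count Poisson(rate·T/1000), times uniform);
    inactive channels are silent.  Familiar stimuli re-encoded from the
    same pattern share only the active-channel set, never spike times.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng()
    mean_count = rate * duration / 1000.0
    times: list[np.ndarray] = []
    for bit in pattern.bits:
        if bit:
            n = rng.poisson(mean_count)
            times.append(np.sort(rng.uniform(0.0, duration, size=n)))
        else:
            times.append(np.empty(0))
    return InputSpikeTrain(times, rate, duration, dt)


# ---------------------------------------------------------------------------
# plain-text readers/writers


def write_dataset(ds: FamiliarityDataset, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
    rows = [
        {
            "index": t,
            "label": int(ds.labels[t]),
            "source_index": int(ds.source_index[t]),
            "bits": "".join(map(str, ds.stimuli[t].bits.tolist())),
        }
        for t in range(len(ds))
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if meta_path is not None and ds.config is not None:
        Path(meta_path).write_text(json.dumps(ds.config.__dict__, indent=2))


def read_dataset(csv_path: str | Path, meta_path: str | Path | None = None) -> FamiliarityDataset:
    df = pd.read_csv(csv_path, dtype={"bits": str})
    stimuli = [BinaryPattern(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")) for s in df["bits"]]
    cfg = None
    if meta_path is not None:
        cfg = DatasetConfig(**json.loads(Path(meta_path).read_text()))
    return FamiliarityDataset(
        stimuli,
        df["label"].to_numpy(dtype=np.int8),
        df["source_index"].to_numpy(dtype=np.int64),
        cfg,
    )


def write_spike_train(train: InputSpikeTrain, path: str | Path) -> None:
    """Plain-text per-channel format: ``neuron_id: t1 t2 ...``."""
    with open(path, "w") as fh:
        for i, t in enumerate(train.times):
            fh.write(f"{i}: " + " ".join(f"{x:.6f}" for x in t) + "\n")


def read_spike_train(path: str | Path, rate: float, duration: float, dt: float = 1.0) -> InputSpikeTrain:
    times = []
    with open(path) as fh:
        for line in fh:
            _, _, rest = line.partition(":")
            vals = np.array([float(x) for x in rest.split()]) if rest.strip() else np.empty(0)
            times.append(vals)
    return InputSpikeTrain(times, rate, duration, dt)
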