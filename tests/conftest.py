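import numpy as np
import pytest

from spikefam.plasticity import PlasticityParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tuned_hebbian():
    """Hand-tuned Hebbian set showing robust familiarity detection at sparseness 0.9."""
    return PlasticityParams(
        rule="hebbian", eta=0.5, tau_a=60.0, a_inc=1.0, W_total=50.0, norm_interval=1000
    )


# ---------------------------------------------------------------------------
# independent brute-force graph oracles (used by unit and acceptance tests)


def brute_transitivity(adj: np.ndarray) -> float:
    """3·triangles / connected triples, by direct enumeration."""
    from itertools import combinations, permutations

    n = adj.shape[0]
    triangles = sum(
        1
        for i, j, k in combinations(range(n), 3)
        if adj[i, j] and adj[j, k] and adj[i, k]
    )
    triples = sum(
        1
        for i, j, k in permutations(range(n), 3)
        if i < k and adj[i, j] and adj[j, k]
    )
    return 0.0 if triples == 0 else 3.0 * triangles / triples


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized shortest-path betweenness by exhaustive simple-path search."""
    from itertools import combinations

    n = adj.shape[0]

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nxt in range(n):
                if adj[node, nxt] and nxt not in path:
                    stack.append((nxt, path + [nxt]))
        return paths

    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            bc[v] += through / len(sp)
    if n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def brute_gini(x: np.ndarray) -> float:
    """Gini by the pairwise-difference definition sum|xi-xj| / (2 n^2 mean)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2.0 * n * n * x.mean()))
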