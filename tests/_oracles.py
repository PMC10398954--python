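"""Independent brute-force oracles shared by the unit and acceptance suites.

These deliberately use naive triple loops / Floyd-Warshall rather than the
package's vectorized implementations, so agreement is a genuine cross-check.
"""

import numpy as np


def brute_clustering(w: np.ndarray, formula: str = "bct") -> float:
    n = w.shape[0]
    scaled = w / w.max() if (formula == "bct" and w.max() > 0) else w
    total = 0.0
    for i in range(n):
        num = 0.0
        for j in range(n):
            for k in range(n):
                if i != j and i != k and j != k:
                    num += (scaled[i, j] * scaled[i, k] * scaled[j, k]) ** (1 / 3)
        if formula == "bct":
            deg = np.sum(w[i] > 0)
            denom = deg * (deg - 1)
        else:
            s = w[i].sum()
            denom = s * (s - 1)
        if denom > 0:
            total += num / denom
    return total / n


def brute_path_length(w: np.ndarray) -> float:
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[w > 0] = 1.0 / w[w > 0]
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    assert np.isfinite(dist).all(), "oracle expects a connected graph"
    off = dist[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    return float(off.mean())


def random_connected_graph(rng: np.random.Generator, n: int) -> np.ndarray:
    w = np.triu(rng.uniform(0.05, 1.0, (n, n)), 1)
    drop = np.triu(rng.random((n, n)) < 0.2, 1)
    w[drop] = 0.0
    w = w + w.T
    # ensure connectivity through a random spanning chain
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if w[a, b] == 0:
            w[a, b] = w[b, a] = rng.uniform(0.05, 1.0)
    return w
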