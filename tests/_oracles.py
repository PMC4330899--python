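"""Independent brute-force oracles used only by the test suite.

Deliberately naive: exhaustive simple-path enumeration for distances,
explicit loops for variance decompositions — no code shared with the
package's implementations.
"""

import itertools

import numpy as np


def brute_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest distance (edge length 1/weight) by enumerating
    every simple path."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            others = [k for k in range(n) if k not in (i, j)]
            best = np.inf
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    path = (i, *mid, j)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / w[a, b]
                    if ok and length < best:
                        best = length
            dist[i, j] = best
    return dist


def brute_global_efficiency(w: np.ndarray) -> float:
    d = brute_distances(w)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_char_path_length(w: np.ndarray) -> float:
    d = brute_distances(w)
    n = w.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def brute_nodal_efficiency(w: np.ndarray) -> np.ndarray:
    d = brute_distances(w)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                out[i] += 1.0 / d[i, j]
    return out / (n - 1)


def brute_binary_clustering(w: np.ndarray) -> float:
    """Binary clustering by triangle counting over explicit node triples."""
    a = (w > 0).astype(int)
    n = a.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        tri = 0
        for x in range(k):
            for y in range(x + 1, k):
                if a[nbrs[x], nbrs[y]]:
                    tri += 1
        cs.append(2.0 * tri / (k * (k - 1)))
    return float(np.mean(cs))


def icc_oracle(y: np.ndarray) -> float:
    """One-way random-effects ICC by explicit loop-based ANOVA."""
    y = np.asarray(y, dtype=float)
    n, m = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(m)) / (n * m)
    row_means = [sum(y[i, j] for j in range(m)) / m for i in range(n)]
    ss_b = sum(m * (rm - grand) ** 2 for rm in row_means)
    ms_b = ss_b / (n - 1)
    ss_w = sum((y[i, j] - row_means[i]) ** 2 for i in range(n) for j in range(m))
    ms_w = ss_w / (n * (m - 1))
    denom = ms_b + (m - 1) * ms_w
    if denom == 0:
        return 0.0
    return (ms_b - ms_w) / denom
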