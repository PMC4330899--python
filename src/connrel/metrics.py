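"""Global and nodal graph metrics for weighted structural networks.

Conventions follow the standard weighted-network definitions used for
fiber-count connectomes (Rubinov & Sporns style):

- Edge length for shortest paths is the reciprocal of the weight,
  ``l_ij = 1 / w_ij`` — strong connections are short.  Disconnected pairs
  have infinite distance, contribute 0 to efficiency, and are excluded
  from the characteristic path length (flagged).
- Network strength Sp is the mean nodal strength (sum available via
  ``sp_mode="sum"``).
- Clustering uses the Onnela geometric-mean triangle form; weights are
  normalized by the network maximum by default, with a raw-weight variant
  for magnitude-preserving analyses.
- Small-world parameters lambda = Lp / <Lp_null>, gamma = Cp / <Cp_null>,
  sigma = gamma / lambda, against an ensemble of degree-preserving
  rewired nulls that carry weights with their edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .netbuild import ConnectomeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullEnsembleConfig",
    "nodal_strength",
    "shortest_distances",
    "global_efficiency",
    "char_path_length",
    "clustering_coefficient",
    "local_efficiency",
    "nodal_efficiency",
    "rewire_null",
    "small_world",
    "global_metrics",
]

GLOBAL_METRIC_NAMES = ("Sp", "Eglob", "Eloc", "Lp", "Cp", "lambda", "gamma", "sigma")
FIRST_ORDER = ("Sp", "Eglob", "Eloc", "Lp", "Cp")
SECOND_ORDER = ("lambda", "gamma", "sigma")


@dataclass
class NullEnsembleConfig:
    """Size and seeding of the degree-preserving null ensemble."""

    n_nulls: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass
class GlobalMetrics:
    """Bundle of the eight global metrics plus null-ensemble diagnostics."""

    sp: float
    eglob: float
    eloc: float
    lp: float
    cp: float
    lambda_: float
    gamma: float
    sigma: float
    n_nulls: int
    connectedness_flag: bool
    null_lp_mean: float = float("nan")
    null_lp_sd: float = float("nan")
    null_cp_mean: float = float("nan")
    null_cp_sd: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "Sp": self.sp,
            "Eglob": self.eglob,
            "Eloc": self.eloc,
            "Lp": self.lp,
            "Cp": self.cp,
            "lambda": self.lambda_,
            "gamma": self.gamma,
            "sigma": self.sigma,
        }


@dataclass
class NodalMetrics:
    """Per-node strength and efficiency."""

    node_labels: list[str]
    strength: np.ndarray
    efficiency: np.ndarray


def _as_weights(matrix: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ConnectomeMatrix):
        return matrix.weights
    return np.asarray(matrix, dtype=float)


def nodal_strength(matrix: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Nodal strength ``s_i = sum_j w_ij`` (row sums)."""
    return _as_weights(matrix).sum(axis=1)


def shortest_distances(matrix: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """All-pairs shortest distances with edge length 1/weight.

    Unreachable pairs get ``inf``; the diagonal is 0.
    """
    w = _as_weights(matrix)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    graph = csr_matrix(lengths)
    return dijkstra(graph, directed=False)


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(dist)
    finite = off & np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv[off].sum() / (n * (n - 1))


def global_efficiency(matrix: ConnectomeMatrix | np.ndarray) -> float:
    """Mean of 1/d over ordered node pairs (disconnected pairs contribute 0)."""
    w = _as_weights(matrix)
    if w.shape[0] < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    return _efficiency_from_distances(shortest_distances(w))


def char_path_length(matrix: ConnectomeMatrix | np.ndarray) -> float:
    """Mean shortest distance over connected ordered pairs.

    Returns ``nan`` when no pair is connected (edgeless graph); callers
    should treat that as an undefined-metric flag, not an error.
    """
    w = _as_weights(matrix)
    if w.shape[0] < 2:
        raise ValueError("characteristic path length requires at least 2 nodes")
    dist = shortest_distances(w)
    off = ~np.eye(dist.shape[0], dtype=bool)
    finite = off & np.isfinite(dist)
    if not finite.any():
        return float("nan")
    return float(dist[finite].mean())


def is_fully_connected(matrix: ConnectomeMatrix | np.ndarray) -> bool:
    dist = shortest_distances(matrix)
    return bool(np.isfinite(dist).all())


def _clustering_per_node(w: np.ndarray, normalize_weights: bool) -> np.ndarray:
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    what = w / wmax if normalize_weights else w
    a13 = np.cbrt(what)
    k = (w > 0).sum(axis=1)
    n = w.shape[0]
    density = (w > 0).sum() / max(1, n * (n - 1))
    if n > 400 and density < 0.1:
        s = csr_matrix(a13)
        tri = np.asarray((s @ s).multiply(s).sum(axis=1)).ravel()
    else:
        tri = np.einsum("ij,jk,ki->i", a13, a13, a13)
    out = np.zeros(n)
    ok = k >= 2
    out[ok] = tri[ok] / (k[ok] * (k[ok] - 1))
    return out


def clustering_coefficient(
    matrix: ConnectomeMatrix | np.ndarray,
    normalize_weights: bool = True,
    per_node: bool = False,
):
    """Onnela weighted clustering coefficient.

    ``C_i = (1/(k_i (k_i - 1))) * sum_{j != h} (w^_ij w^_ih w^_jh)^(1/3)``
    with ``w^`` the weights divided by the network maximum when
    ``normalize_weights`` (default) or raw otherwise.  Nodes with degree
    < 2 contribute 0.  Returns the network mean, or the per-node vector
    when ``per_node``.
    """
    w = _as_weights(matrix)
    c = _clustering_per_node(w, normalize_weights)
    return c if per_node else float(c.mean())


def local_efficiency(matrix: ConnectomeMatrix | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighborhood subgraph.

    Weights inside the neighborhood are retained; nodes with fewer than
    two neighbors contribute 0.
    """
    w = _as_weights(matrix)
    n = w.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(w[i])[0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        vals[i] = _efficiency_from_distances(shortest_distances(sub))
    return float(vals.mean())


def nodal_efficiency(matrix: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Per-node efficiency ``E_nodal(i) = (1/(N-1)) sum_{j != i} 1/d_ij``."""
    w = _as_weights(matrix)
    n = w.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    dist = shortest_distances(w)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(dist)
    finite = off & np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv.sum(axis=1) / (n - 1)


def nodal_metrics(matrix: ConnectomeMatrix) -> NodalMetrics:
    return NodalMetrics(
        list(matrix.node_labels), nodal_strength(matrix), nodal_efficiency(matrix)
    )


def rewire_null(
    matrix: ConnectomeMatrix | np.ndarray,
    swaps_per_edge: int = 10,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One degree-preserving rewired null; weights travel with their edges.

    Attempts ``swaps_per_edge * E`` double-edge swaps, rejecting proposals
    that would create self-loops or multi-edges.  The binarized degree
    sequence and the weight multiset of the input are preserved exactly.
    Returns the null weight matrix.
    """
    w = _as_weights(matrix)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    iu, ju = np.nonzero(np.triu(w, 1))
    n_edges = len(iu)
    if n_edges < 2:
        logger.warning("rewire_null: fewer than 2 edges, returning a copy")
        return w.copy()
    u = iu.copy()
    v = ju.copy()
    wts = w[iu, ju].copy()
    edge_set = {(int(a), int(b)) for a, b in zip(u, v)}

    n_attempts = swaps_per_edge * n_edges
    pick = rng.integers(0, n_edges, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if flip[t]:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        u[e1], v[e1] = new1
        u[e2], v[e2] = new2
    out = np.zeros_like(w)
    out[u, v] = wts
    out[v, u] = wts
    return out


@dataclass
class SmallWorldResult:
    lambda_: float
    gamma: float
    sigma: float
    null_lp_mean: float
    null_lp_sd: float
    null_cp_mean: float
    null_cp_sd: float
    n_nulls_used: int


def small_world(
    matrix: ConnectomeMatrix | np.ndarray,
    config: NullEnsembleConfig | None = None,
    normalize_weights: bool = True,
) -> SmallWorldResult:
    """Small-world parameters against a seeded rewired null ensemble.

    lambda = Lp / <Lp_null>, gamma = Cp / <Cp_null>, sigma = gamma /
    lambda.  Nulls with zero clustering are excluded with a warning; if
    every null is excluded an error is raised.
    """
    if config is None:
        config = NullEnsembleConfig()
    w = _as_weights(matrix)
    lp = char_path_length(w)
    cp = clustering_coefficient(w, normalize_weights=normalize_weights)
    children = np.random.SeedSequence(config.seed).spawn(config.n_nulls)
    lps, cps = [], []
    for child in children:
        null = rewire_null(w, config.swaps_per_edge, np.random.default_rng(child))
        cp_k = clustering_coefficient(null, normalize_weights=normalize_weights)
        if cp_k == 0:
            logger.warning("small_world: null with zero clustering excluded")
            continue
        lps.append(char_path_length(null))
        cps.append(cp_k)
    if not cps:
        raise ValueError("small_world: every null had zero clustering")
    lp_mean, cp_mean = float(np.mean(lps)), float(np.mean(cps))
    lam = lp / lp_mean
    gam = cp / cp_mean
    return SmallWorldResult(
        lambda_=lam,
        gamma=gam,
        sigma=gam / lam,
        null_lp_mean=lp_mean,
        null_lp_sd=float(np.std(lps)),
        null_cp_mean=cp_mean,
        null_cp_sd=float(np.std(cps)),
        n_nulls_used=len(cps),
    )


def global_metrics(
    matrix: ConnectomeMatrix | np.ndarray,
    config: NullEnsembleConfig | None = None,
    sp_mode: str = "mean",
    normalize_weights: bool = True,
) -> GlobalMetrics:
    """Compute the full set of global metrics for one network."""
    if config is None:
        config = NullEnsembleConfig()
    w = _as_weights(matrix)
    s = nodal_strength(w)
    sp = float(s.mean() if sp_mode == "mean" else s.sum())
    sw = small_world(w, config, normalize_weights=normalize_weights)
    return GlobalMetrics(
        sp=sp,
        eglob=global_efficiency(w),
        eloc=local_efficiency(w),
        lp=char_path_length(w),
        cp=clustering_coefficient(w, normalize_weights=normalize_weights),
        lambda_=sw.lambda_,
        gamma=sw.gamma,
        sigma=sw.sigma,
        n_nulls=sw.n_nulls_used,
        connectedness_flag=is_fully_connected(w),
        null_lp_mean=sw.null_lp_mean,
        null_lp_sd=sw.null_lp_sd,
        null_cp_mean=sw.null_cp_mean,
        null_cp_sd=sw.null_cp_sd,
    )
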