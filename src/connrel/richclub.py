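"""Rich-club organization: hubs, edge categories, normalized coefficients.

Hubs are nodes whose strength exceeds the network mean plus one standard
deviation.  Edges are partitioned into rich-club (hub-hub), feeder
(hub-nonhub) and local (nonhub-nonhub) connections.  The weighted
rich-club coefficient phi at a strength threshold is the weight captured
inside the rich set divided by the sum of the equally many strongest
weights anywhere in the network; it is normalized against
degree-preserving rewired nulls, whose thresholds are recomputed from
each null's own strengths by default (strengths change under rewiring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import NullEnsembleConfig, nodal_strength, rewire_null
from .netbuild import ConnectomeMatrix

__all__ = [
    "RichClubProfile",
    "RichClubValue",
    "classify_hubs",
    "classify_edges",
    "rich_club_coeff",
    "normalized_rich_club",
]

EDGE_CATEGORIES = ("rich_club", "feeder", "local")


def _std(values: np.ndarray, population: bool) -> float:
    return float(np.std(values, ddof=0 if population else 1))


def classify_hubs(strengths: np.ndarray, population_std: bool = True) -> np.ndarray:
    """Hub flags: nodal strength > mean + std.

    Population (divide-by-N) standard deviation by default; sample std via
    ``population_std=False``.  Constant strengths yield no hubs.
    """
    strengths = np.asarray(strengths, dtype=float)
    if strengths.size < 2:
        raise ValueError("hub classification requires at least 2 nodes")
    thr = strengths.mean() + _std(strengths, population_std)
    return strengths > thr


def classify_edges(
    matrix: ConnectomeMatrix | np.ndarray, hub_flags: np.ndarray
) -> np.ndarray:
    """Label every edge rich_club / feeder / local by its endpoints' hub status.

    Returns an (N, N) object array with category strings on edges and
    ``None`` elsewhere; the three categories partition the edge set.
    """
    w = matrix.weights if isinstance(matrix, ConnectomeMatrix) else np.asarray(matrix)
    hub_flags = np.asarray(hub_flags, dtype=bool)
    if hub_flags.size != w.shape[0]:
        raise ValueError("hub flags must cover all nodes")
    n_hub_ends = hub_flags[:, None].astype(int) + hub_flags[None, :].astype(int)
    cats = np.full(w.shape, None, dtype=object)
    edge = w > 0
    cats[edge & (n_hub_ends == 2)] = "rich_club"
    cats[edge & (n_hub_ends == 1)] = "feeder"
    cats[edge & (n_hub_ends == 0)] = "local"
    return cats


@dataclass
class RichClubValue:
    phi: float
    n_rich_nodes: int
    n_rich_edges: int
    defined: bool


def rich_club_coeff(
    matrix: ConnectomeMatrix | np.ndarray, threshold: float
) -> RichClubValue:
    """Weighted rich-club coefficient at one strength cutoff.

    With rich set ``R = {i : s_i > threshold}``, ``phi`` is the total
    weight inside R divided by the sum of the |edges in R| largest edge
    weights in the whole network, so ``phi`` lies in [0, 1] where defined.
    Undefined (no edges inside R) is flagged, never coerced to 0 — the
    analogue of a "-" cell in a thresholded rich-club table.
    """
    w = matrix.weights if isinstance(matrix, ConnectomeMatrix) else np.asarray(matrix)
    s = nodal_strength(w)
    rich = s > threshold
    sub = w[np.ix_(rich, rich)]
    triu_sub = np.triu(sub, 1)
    n_rich_edges = int(np.count_nonzero(triu_sub))
    if n_rich_edges == 0:
        return RichClubValue(float("nan"), int(rich.sum()), 0, False)
    w_r = triu_sub.sum()
    all_w = np.sort(np.triu(w, 1)[np.triu(w, 1) > 0])[::-1]
    phi = float(w_r / all_w[:n_rich_edges].sum())
    return RichClubValue(phi, int(rich.sum()), n_rich_edges, True)


@dataclass
class RichClubProfile:
    """phi and normalized phi over the mean + k*std threshold grid."""

    k_values: list[float]
    thresholds: list[float]
    phi: list[float]
    phi_norm: list[float]
    null_phi_mean: list[float]
    null_phi_sd: list[float]
    n_rich_nodes: list[int]
    n_rich_edges: list[int]
    defined: list[bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "threshold": self.thresholds,
                "phi": self.phi,
                "phi_norm": self.phi_norm,
                "null_phi_mean": self.null_phi_mean,
                "null_phi_sd": self.null_phi_sd,
                "n_rich_nodes": self.n_rich_nodes,
                "n_rich_edges": self.n_rich_edges,
                "defined": self.defined,
            }
        )


def normalized_rich_club(
    matrix: ConnectomeMatrix | np.ndarray,
    k_values: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5),
    null_config: NullEnsembleConfig | None = None,
    per_null_thresholds: bool = True,
    population_std: bool = True,
) -> RichClubProfile:
    """Normalized rich-club coefficient over mean + k*std strength cutoffs.

    ``phi_norm(k) = phi(k) / <phi_null(k)>`` with each null's phi computed
    at that null's own strength-derived threshold when
    ``per_null_thresholds`` (default), or at the original network's
    thresholds otherwise.  An undefined phi, or all nulls undefined at a
    threshold, propagates as an undefined (flagged) cell.
    """
    if null_config is None:
        null_config = NullEnsembleConfig()
    w = matrix.weights if isinstance(matrix, ConnectomeMatrix) else np.asarray(matrix)
    s = nodal_strength(w)
    mean, std = s.mean(), _std(s, population_std)
    k_values = [float(k) for k in k_values]
    thresholds = [mean + k * std for k in k_values]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing (std is zero?)")

    observed = [rich_club_coeff(w, thr) for thr in thresholds]

    children = np.random.SeedSequence(null_config.seed).spawn(null_config.n_nulls)
    null_phis: list[list[float]] = [[] for _ in k_values]
    for child in children:
        null = rewire_null(w, null_config.swaps_per_edge, np.random.default_rng(child))
        if per_null_thresholds:
            s_null = nodal_strength(null)
            m_n, sd_n = s_null.mean(), _std(s_null, population_std)
            thrs = [m_n + k * sd_n for k in k_values]
        else:
            thrs = thresholds
        for idx, thr in enumerate(thrs):
            val = rich_club_coeff(null, thr)
            if val.defined:
                null_phis[idx].append(val.phi)

    phi_norm, null_mean, null_sd, defined = [], [], [], []
    for idx, obs in enumerate(observed):
        phis = null_phis[idx]
        if obs.defined and phis:
            mu = float(np.mean(phis))
            phi_norm.append(obs.phi / mu)
            null_mean.append(mu)
            null_sd.append(float(np.std(phis)))
            defined.append(True)
        else:
            phi_norm.append(float("nan"))
            null_mean.append(float(np.mean(phis)) if phis else float("nan"))
            null_sd.append(float(np.std(phis)) if phis else float("nan"))
            defined.append(False)

    return RichClubProfile(
        k_values=k_values,
        thresholds=[float(t) for t in thresholds],
        phi=[o.phi for o in observed],
        phi_norm=phi_norm,
        null_phi_mean=null_mean,
        null_phi_sd=null_sd,
        n_rich_nodes=[o.n_rich_nodes for o in observed],
        n_rich_edges=[o.n_rich_edges for o in observed],
        defined=defined,
    )
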