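"""Construction of fiber-number-weighted structural brain networks.

Networks are built from streamline endpoint tables: each tractography
streamline contributes one record holding the two cortical parcels its
endpoints fall in.  Two regions are connected if at least one streamline
ends in both, and the edge weight is the streamline (fiber) count.
Streamlines with both endpoints in the same parcel do not form an edge;
they are counted and logged for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectomeMatrix",
    "Parcellation",
    "StreamlineEndpointTable",
    "build_network",
    "binarize",
    "coarsen_network",
    "sparsity",
]


def _validate_weights(weights: np.ndarray) -> None:
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {weights.shape}")
    if not np.all(np.isfinite(weights)):
        raise ValueError("weight matrix contains non-finite entries")
    if np.any(weights < 0):
        i, j = np.argwhere(weights < 0)[0]
        raise ValueError(f"negative weight at ({i}, {j})")
    if not np.allclose(weights, weights.T):
        i, j = np.argwhere(~np.isclose(weights, weights.T))[0]
        raise ValueError(f"weight matrix not symmetric at ({i}, {j})")
    if np.any(np.diag(weights) != 0):
        raise ValueError("weight matrix must have a zero diagonal")


@dataclass
class ConnectomeMatrix:
    """Symmetric nonnegative weighted adjacency with node labels.

    Attributes
    ----------
    node_labels : list of str
        Node names; matrix rows/columns follow this order.
    weights : ndarray of shape (N, N)
        Fiber-number weights (or 0/1 after binarization).  Symmetric,
        zero diagonal, nonnegative, finite.
    resolution_tag : {"low", "high"}
        Nodal scale of the parcellation the matrix was built on.
    parcellation_tag : str
        Free-text provenance (e.g. parcellation name).
    """

    node_labels: list[str]
    weights: np.ndarray
    resolution_tag: str = "low"
    parcellation_tag: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.node_labels) != self.weights.shape[0]:
            raise ValueError("node_labels length does not match matrix size")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        _validate_weights(self.weights)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def copy(self) -> "ConnectomeMatrix":
        return ConnectomeMatrix(
            list(self.node_labels),
            self.weights.copy(),
            self.resolution_tag,
            self.parcellation_tag,
        )


@dataclass
class Parcellation:
    """Node set with regional-class labels and an optional coarsening map.

    ``node_class`` maps each label to one of {association, primary,
    paralimbic}; ``low_res_group`` maps high-resolution labels to the
    low-resolution parcel they subdivide.
    """

    labels: list[str]
    node_class: dict[str, str] = field(default_factory=dict)
    low_res_group: dict[str, str] | None = None

    REGIONAL_CLASSES = ("association", "primary", "paralimbic")

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("parcellation labels must be unique")
        for lab, cls in self.node_class.items():
            if cls not in self.REGIONAL_CLASSES:
                raise ValueError(f"unknown regional class {cls!r} for node {lab!r}")


@dataclass
class StreamlineEndpointTable:
    """One record per streamline: the parcel labels at its two endpoints."""

    records: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.records)


def build_network(
    endpoints: StreamlineEndpointTable,
    parcellation: Parcellation,
    min_streamlines: int = 1,
) -> ConnectomeMatrix:
    """Count streamlines per region pair into a fiber-number matrix.

    Records with both endpoints in one parcel (self-connections) are
    excluded from the edge weights and logged.  Edges with fewer than
    ``min_streamlines`` streamlines are zeroed (default 1, i.e. the plain
    at-least-one-fiber existence rule).
    """
    labels = list(parcellation.labels)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    weights = np.zeros((n, n))
    n_self = 0
    for a, b in endpoints.records:
        if a not in index:
            raise KeyError(f"endpoint label {a!r} not in parcellation")
        if b not in index:
            raise KeyError(f"endpoint label {b!r} not in parcellation")
        if a == b:
            n_self += 1
            continue
        i, j = index[a], index[b]
        weights[i, j] += 1
        weights[j, i] += 1
    if n_self:
        logger.info("build_network: excluded %d self-connection records", n_self)
    if not endpoints.records:
        logger.warning("build_network: empty endpoint table, all-zero matrix")
    if min_streamlines > 1:
        weights[weights < min_streamlines] = 0.0
    return ConnectomeMatrix(labels, weights)


def binarize(matrix: ConnectomeMatrix) -> ConnectomeMatrix:
    """Replace every positive weight with 1 (idempotent)."""
    out = matrix.copy()
    out.weights = (out.weights > 0).astype(float)
    return out


def coarsen_network(
    matrix: ConnectomeMatrix, low_res_group: dict[str, str]
) -> ConnectomeMatrix:
    """Aggregate a high-resolution matrix to the low-resolution node set.

    The low-resolution weight between two groups is the sum of all
    high-resolution weights across the group pair.  Weights between two
    members of the same group would land on the diagonal and are dropped
    (their total is logged), matching the zero-diagonal rule.
    """
    for lab in matrix.node_labels:
        if lab not in low_res_group:
            raise KeyError(f"label {lab!r} missing from low_res_group map")
    # preserve first-appearance order of the low-resolution groups
    low_labels: list[str] = []
    for lab in matrix.node_labels:
        g = low_res_group[lab]
        if g not in low_labels:
            low_labels.append(g)
    gidx = {g: k for k, g in enumerate(low_labels)}
    assign = np.array([gidx[low_res_group[lab]] for lab in matrix.node_labels])
    n_low = len(low_labels)
    # indicator matrix aggregation: W_low = A^T W A
    A = np.zeros((matrix.n_nodes, n_low))
    A[np.arange(matrix.n_nodes), assign] = 1.0
    full = A.T @ matrix.weights @ A
    within = np.trace(full) / 2.0
    if within > 0:
        logger.info("coarsen_network: dropped within-group weight %g", within)
    np.fill_diagonal(full, 0.0)
    return ConnectomeMatrix(
        low_labels, full, resolution_tag="low", parcellation_tag=matrix.parcellation_tag
    )


def sparsity(matrix: ConnectomeMatrix) -> float:
    """Fraction of possible node pairs that are connected."""
    n = matrix.n_nodes
    if n < 2:
        raise ValueError("sparsity requires at least 2 nodes")
    n_edges = int(np.count_nonzero(np.triu(matrix.weights, 1)))
    return n_edges / (n * (n - 1) / 2)
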