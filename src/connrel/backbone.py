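"""Group backbone extraction by a one-tailed sign test.

For each candidate edge and scanning session, the null hypothesis is that
no connection exists (fiber count 0).  Subjects with a zero count are
ties and are discarded — the standard sign-test convention — so with k
subjects showing a nonzero count the one-tailed p-value is 0.5**k (p = 1
when k = 0).  Edges significant at ``alpha`` in at least one session
(rule "either", the default) or in every session (rule "both") survive
and carry the mean weight over all subjects x sessions; all other edges
are zeroed.  With 11 subjects and alpha 0.05 the survival boundary is
k >= 5 (0.5**5 = 0.03125 < 0.05 <= 0.5**4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .synthgen import TRTDataset

__all__ = ["BackboneNetwork", "sign_test_p", "build_backbone"]


def sign_test_p(n_nonzero: int, n_subjects: int) -> float:
    """One-tailed sign-test p-value for an edge seen in ``n_nonzero`` subjects."""
    if not (0 <= n_nonzero <= n_subjects):
        raise ValueError("n_nonzero must be between 0 and n_subjects")
    if n_nonzero == 0:
        return 1.0
    return 0.5 ** n_nonzero


@dataclass
class BackboneNetwork:
    """Sign-test-surviving edges with group-averaged weights."""

    node_labels: list[str]
    mean_weights: np.ndarray          # (N, N); zero off the backbone
    p_values: np.ndarray              # (n_sessions, N, N)
    survived: np.ndarray              # (N, N) bool
    alpha: float
    session_rule: str

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.survived, 1)))

    def edge_table(self) -> pd.DataFrame:
        iu, ju = np.nonzero(np.triu(self.survived, 1))
        rows = {
            "node_a": [self.node_labels[i] for i in iu],
            "node_b": [self.node_labels[j] for j in ju],
            "mean_weight": self.mean_weights[iu, ju],
        }
        for s in range(self.p_values.shape[0]):
            rows[f"p_session{s + 1}"] = self.p_values[s, iu, ju]
        return pd.DataFrame(rows)


def build_backbone(
    dataset: TRTDataset,
    alpha: float = 0.05,
    session_rule: str = "either",
    fdr: bool = False,
) -> BackboneNetwork:
    """Extract the group backbone of consistently present connections.

    ``fdr`` applies Benjamini-Hochberg control across candidate edges
    within each session before thresholding (off by default, matching a
    plain per-edge p < alpha rule).
    """
    if session_rule not in ("either", "both"):
        raise ValueError(f"unknown session_rule {session_rule!r}")
    if dataset.n_subjects < 2:
        raise ValueError("backbone extraction requires at least 2 subjects")
    arr = dataset.to_array()  # (n, m, N, N)
    n, m, n_nodes, _ = arr.shape
    counts = (arr > 0).sum(axis=0)  # (m, N, N)
    p = np.where(counts > 0, 0.5 ** counts, 1.0)

    sig = np.ones((m, n_nodes, n_nodes), dtype=bool)
    iu, ju = np.triu_indices(n_nodes, 1)
    for s in range(m):
        ps = p[s, iu, ju]
        if fdr:
            ps = false_discovery_control(ps, method="bh")
        edge_sig = ps < alpha
        sig_s = np.zeros((n_nodes, n_nodes), dtype=bool)
        sig_s[iu, ju] = edge_sig
        sig_s[ju, iu] = edge_sig
        sig[s] = sig_s

    survived = sig.any(axis=0) if session_rule == "either" else sig.all(axis=0)
    np.fill_diagonal(survived, False)
    mean_w = arr.mean(axis=(0, 1)) * survived
    return BackboneNetwork(
        node_labels=list(dataset.node_labels),
        mean_weights=mean_w,
        p_values=p,
        survived=survived,
        alpha=alpha,
        session_rule=session_rule,
    )
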