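"""Synthetic test-retest connectome generator with known variance components.

The generator emulates the derived products of a two-session diffusion-MRI
study: per-subject, per-session fiber-count networks over a shared
parcellation, with a core-periphery (rich-club) topology, heavy-tailed
integer edge weights, realistic sparsity, and separable between-subject vs
within-subject (session) variance.  Because the variance components are
known by construction, every downstream reliability estimator can be
validated against closed-form population values.

All randomness flows from one top-level seed through named
``numpy.random.SeedSequence`` substreams (structure, weights, classes,
subjects, sessions, dropout), so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .netbuild import ConnectomeMatrix, StreamlineEndpointTable

__all__ = [
    "TemplateNetwork",
    "TRTConfig",
    "TRTDataset",
    "make_template",
    "subdivide_template",
    "simulate_trt",
    "simulate_endpoints",
]

REGIONAL_CLASSES = ("association", "primary", "paralimbic")
# rough cortical proportions of the three regional classes
CLASS_PROPORTIONS = (0.5, 0.3, 0.2)

# named substream indices off the top-level seed
_SUB_STRUCTURE, _SUB_WEIGHTS, _SUB_CLASSES, _SUB_SUBJECTS, _SUB_SESSIONS, _SUB_DROPOUT = range(6)


def _substream(seed: int, which: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(which,)))


@dataclass
class TemplateNetwork:
    """Ground-truth expected network: mean fiber counts plus node metadata.

    ``mean_weight[i, j]`` is the expected fiber number mu_e of edge (i, j);
    zero means structurally absent.  ``core_flag`` marks rich-club core
    membership, ``node_class`` assigns the regional class used for grouped
    reliability summaries.
    """

    node_labels: list[str]
    node_class: dict[str, str]
    core_flag: np.ndarray
    mean_weight: np.ndarray
    target_density: float

    def __post_init__(self) -> None:
        self.core_flag = np.asarray(self.core_flag, dtype=bool)
        self.mean_weight = np.asarray(self.mean_weight, dtype=float)
        n = len(self.node_labels)
        if self.mean_weight.shape != (n, n):
            raise ValueError("mean_weight shape does not match node count")
        if not np.allclose(self.mean_weight, self.mean_weight.T):
            raise ValueError("mean_weight must be symmetric")
        if np.any(np.diag(self.mean_weight) != 0):
            raise ValueError("mean_weight must have a zero diagonal")
        if np.any(self.mean_weight < 0):
            raise ValueError("mean_weight must be nonnegative")
        if self.core_flag.sum() < 1:
            raise ValueError("template must have at least one core node")
        if not (abs(self.density - self.target_density) <= 0.2 * self.target_density):
            raise ValueError(
                f"realized density {self.density:.4f} outside +/-20% of "
                f"target {self.target_density:.4f}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def density(self) -> float:
        n = self.n_nodes
        return np.count_nonzero(np.triu(self.mean_weight, 1)) / (n * (n - 1) / 2)

    def as_matrix(self, resolution_tag: str = "low") -> ConnectomeMatrix:
        return ConnectomeMatrix(
            list(self.node_labels), self.mean_weight.copy(), resolution_tag, "template"
        )


@dataclass
class TRTConfig:
    """Parameters of a simulated test-retest acquisition.

    ``sigma_bs2``/``sigma_ws2`` are the between-subject and within-subject
    (session) variance components.  Their scale depends on
    ``variance_mode``:

    - ``"relative"`` (default): noise standard deviations are proportional
      to the edge mean (sd = sigma * mu_e), mimicking fiber-count noise
      that grows with bundle size.
    - ``"absolute"``: sd = sigma for every edge; the per-edge population
      intraclass correlation is then exactly
      ``sigma_bs2 / (sigma_bs2 + sigma_ws2)``, enabling exact recovery
      tests.
    - ``"mixed"``: between-subject relative, within-subject absolute —
      strong edges become more reliable than weak ones, reproducing the
      positive weight-vs-reliability relation seen in real connectomes.

    ``noise_model``: ``"gaussian_additive"`` (clamped at 0) or
    ``"lognormal_count"`` (rounded, zero-truncated integer counts with
    log-scale variance components; ``variance_mode`` does not apply).
    """

    n_subjects: int
    n_sessions: int = 2
    sigma_bs2: float = 0.04
    sigma_ws2: float = 0.01
    noise_model: str = "gaussian_additive"
    variance_mode: str = "relative"
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_sessions < 2:
            raise ValueError("n_sessions (m) must be >= 2")
        if self.sigma_bs2 < 0 or self.sigma_ws2 < 0:
            raise ValueError("variance components must be >= 0")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.noise_model not in ("gaussian_additive", "lognormal_count"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.variance_mode not in ("relative", "absolute", "mixed"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")


@dataclass
class TRTDataset:
    """Subjects x sessions collection of connectomes over one node set."""

    node_labels: list[str]
    matrices: list[list[ConnectomeMatrix]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for row in self.matrices:
            for m in row:
                if m.node_labels != self.node_labels:
                    raise ValueError("all matrices must share the dataset node set")

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def n_sessions(self) -> int:
        return len(self.matrices[0]) if self.matrices else 0

    def to_array(self) -> np.ndarray:
        """Stack into an (n_subjects, n_sessions, N, N) array."""
        return np.stack([[m.weights for m in row] for row in self.matrices])


def _edge_probabilities(
    n_cc: int, n_cp: int, n_pp: int, target_density: float
) -> tuple[float, float, float]:
    """Solve for Bernoulli probabilities with 3:2:1 (core-core : core-
    periphery : periphery-periphery) ratios hitting the target density,
    water-filling categories capped at probability 1."""
    total = n_cc + n_cp + n_pp
    need = target_density * total
    if need > total + 1e-9:
        raise ValueError("target_density > 1 is unreachable")
    ratios = np.array([3.0, 2.0, 1.0])
    counts = np.array([n_cc, n_cp, n_pp], dtype=float)
    probs = np.zeros(3)
    capped = np.zeros(3, dtype=bool)
    remaining = need
    for _ in range(3):
        free = ~capped & (counts > 0)
        if not free.any():
            break
        x = remaining / (ratios[free] @ counts[free])
        p = ratios * x
        over = free & (p >= 1.0)
        if not over.any():
            probs[free] = p[free]
            break
        probs[over] = 1.0
        capped |= over
        remaining = need - counts[capped].sum()
    expected = probs @ counts
    if expected < need - 1e-6:
        raise ValueError(
            f"target density {target_density} unreachable with the given "
            f"core_fraction (expected edge count {expected:.1f} < {need:.1f})"
        )
    return tuple(probs)


def make_template(
    n_nodes: int,
    target_density: float = 0.2,
    core_fraction: float = 0.15,
    weight_scale: float = 50.0,
    seed: int = 0,
) -> TemplateNetwork:
    """Build a core-periphery template with lognormal integer weights.

    Edge probabilities follow a 3:2:1 core-core : core-periphery :
    periphery-periphery ratio scaled to the target density, which creates
    a strength-rich core; present edges draw weights from a lognormal law
    with median ``weight_scale`` (doubled on core-core edges) rounded to
    integers >= 1.  Deterministic given ``seed``.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    if not (0 < target_density <= 1):
        raise ValueError("target_density must be in (0, 1]")
    if not (0 < core_fraction < 1):
        raise ValueError("core_fraction must be in (0, 1)")

    n_core = max(1, round(core_fraction * n_nodes))
    core = np.zeros(n_nodes, dtype=bool)
    core[:n_core] = True  # labels are generated fresh, so leading block is fine
    n_cc = n_core * (n_core - 1) // 2
    n_per = n_nodes - n_core
    n_cp = n_core * n_per
    n_pp = n_per * (n_per - 1) // 2
    p_cc, p_cp, p_pp = _edge_probabilities(n_cc, n_cp, n_pp, target_density)

    rng_struct = _substream(seed, _SUB_STRUCTURE)
    iu, ju = np.triu_indices(n_nodes, 1)
    pair_core = core[iu].astype(int) + core[ju].astype(int)  # 0, 1 or 2 core ends
    pair_p = np.choose(pair_core, [p_pp, p_cp, p_cc])
    total_pairs = len(iu)
    adj = None
    for _ in range(20):  # redraw on unlucky density, still deterministic
        draw = rng_struct.random(total_pairs) < pair_p
        realized = draw.sum() / total_pairs
        if abs(realized - target_density) <= 0.2 * target_density:
            adj = draw
            break
    if adj is None:
        raise ValueError("could not realize target density within +/-20%")

    rng_w = _substream(seed, _SUB_WEIGHTS)
    w = np.zeros(total_pairs)
    n_edges = int(adj.sum())
    raw = rng_w.lognormal(mean=np.log(weight_scale), sigma=1.0, size=n_edges)
    raw = np.where(pair_core[adj] == 2, raw * 2.0, raw)
    w[adj] = np.maximum(1, np.round(raw))

    weights = np.zeros((n_nodes, n_nodes))
    weights[iu, ju] = w
    weights[ju, iu] = w

    rng_c = _substream(seed, _SUB_CLASSES)
    width = len(str(n_nodes - 1))
    labels = [f"node{i:0{width}d}" for i in range(n_nodes)]
    classes = rng_c.choice(REGIONAL_CLASSES, size=n_nodes, p=CLASS_PROPORTIONS)
    node_class = dict(zip(labels, classes))

    return TemplateNetwork(labels, node_class, core, weights, target_density)


def subdivide_template(
    template: TemplateNetwork,
    factor: int,
    seed: int = 0,
    concentration: float = 0.035,
) -> tuple[TemplateNetwork, dict[str, str]]:
    """Split every node into ``factor`` equal subnodes, partitioning weights.

    Each low-resolution edge weight is split across the ``factor**2``
    corresponding high-node pairs by a multinomial draw whose cell
    probabilities come from a Dirichlet law with per-cell
    ``concentration``; small concentrations put most streamlines on a few
    subpairs, keeping the high-resolution network sparse the way real
    subdivided parcellations are.  Totals are conserved exactly, so
    coarsening back through the returned node map reproduces the
    low-resolution template.

    Returns the high-resolution template and the high-label -> low-label
    map.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    mu = template.mean_weight
    if not np.allclose(mu, np.round(mu)):
        raise ValueError("subdivision requires integer template weights")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))

    n_low = template.n_nodes
    n_high = n_low * factor
    labels = [f"{lab}.{k}" for lab in template.node_labels for k in range(factor)]
    node_map = {
        f"{lab}.{k}": lab for lab in template.node_labels for k in range(factor)
    }
    high = np.zeros((n_high, n_high))
    for i in range(n_low):
        for j in range(i + 1, n_low):
            w = int(round(mu[i, j]))
            if w == 0:
                continue
            probs = rng.dirichlet(np.full(factor * factor, concentration))
            counts = rng.multinomial(w, probs).reshape(factor, factor)
            high[
                i * factor : (i + 1) * factor, j * factor : (j + 1) * factor
            ] = counts
            high[
                j * factor : (j + 1) * factor, i * factor : (i + 1) * factor
            ] = counts.T

    core = np.repeat(template.core_flag, factor)
    node_class = {h: template.node_class[low] for h, low in node_map.items()}
    realized = np.count_nonzero(np.triu(high, 1)) / (n_high * (n_high - 1) / 2)
    out = TemplateNetwork(labels, node_class, core, high, target_density=realized)
    return out, node_map


def simulate_trt(template: TemplateNetwork, config: TRTConfig) -> TRTDataset:
    """Simulate a subjects x sessions test-retest dataset from a template.

    Gaussian additive model, per present edge e, subject i, session j::

        w_ije = max(0, mu_e + b_ie + eps_ije)
        b_ie  ~ Normal(0, sigma_bs2 * scale_bs(e)^2)   (shared across sessions)
        eps   ~ Normal(0, sigma_ws2 * scale_ws(e)^2)

    with the scales set by ``config.variance_mode`` (see :class:`TRTConfig`).
    Lognormal count model: ``round(exp(log mu_e + b + eps))`` truncated at
    1, with b, eps on the log scale.  Absent edges stay 0; dropout zeroes a
    present edge for one subject-session with ``dropout_prob``.
    """
    mu = template.mean_weight
    n_nodes = template.n_nodes
    iu, ju = np.triu_indices(n_nodes, 1)
    present = mu[iu, ju] > 0
    ie, je = iu[present], ju[present]
    mu_e = mu[ie, je]
    n_e = len(mu_e)
    n, m = config.n_subjects, config.n_sessions

    rng_sub = _substream(config.seed, _SUB_SUBJECTS)
    rng_ses = _substream(config.seed, _SUB_SESSIONS)

    if config.noise_model == "gaussian_additive":
        if config.variance_mode == "relative":
            scale_bs = scale_ws = mu_e
        elif config.variance_mode == "absolute":
            scale_bs = scale_ws = np.ones(n_e)
        else:  # mixed
            scale_bs, scale_ws = mu_e, np.ones(n_e)
        b = rng_sub.standard_normal((n, n_e)) * np.sqrt(config.sigma_bs2) * scale_bs
        eps = (
            rng_ses.standard_normal((n, m, n_e))
            * np.sqrt(config.sigma_ws2)
            * scale_ws
        )
        w = np.maximum(0.0, mu_e[None, None, :] + b[:, None, :] + eps)
    else:  # lognormal_count, variances on the log scale
        b = rng_sub.standard_normal((n, n_e)) * np.sqrt(config.sigma_bs2)
        eps = rng_ses.standard_normal((n, m, n_e)) * np.sqrt(config.sigma_ws2)
        w = np.maximum(1, np.round(np.exp(np.log(mu_e)[None, None, :] + b[:, None, :] + eps)))

    if config.dropout_prob > 0:
        rng_drop = _substream(config.seed, _SUB_DROPOUT)
        w = np.where(rng_drop.random((n, m, n_e)) < config.dropout_prob, 0.0, w)

    tag = "high" if n_nodes > 500 else "low"
    matrices: list[list[ConnectomeMatrix]] = []
    for i in range(n):
        row = []
        for j in range(m):
            full = np.zeros((n_nodes, n_nodes))
            full[ie, je] = w[i, j]
            full[je, ie] = w[i, j]
            row.append(
                ConnectomeMatrix(list(template.node_labels), full, tag, "synthetic")
            )
        matrices.append(row)

    return TRTDataset(
        list(template.node_labels),
        matrices,
        provenance={"generator": "simulate_trt", "config": asdict(config)},
    )


def simulate_endpoints(matrix: ConnectomeMatrix, seed: int = 0) -> StreamlineEndpointTable:
    """Expand an integer fiber-count matrix into shuffled endpoint records.

    Emits exactly ``w_ij`` records per nonzero edge; the round trip through
    :func:`connrel.netbuild.build_network` reproduces the matrix exactly.
    """
    w = matrix.weights
    if not np.allclose(w, np.round(w)):
        raise ValueError(
            "simulate_endpoints requires integer weights; round the matrix first"
        )
    iu, ju = np.nonzero(np.triu(w, 1))
    records: list[tuple[str, str]] = []
    for i, j in zip(iu, ju):
        records.extend(
            [(matrix.node_labels[i], matrix.node_labels[j])] * int(round(w[i, j]))
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20,)))
    rng.shuffle(records)
    return StreamlineEndpointTable(records)
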