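"""Test-retest reliability: the one-way random-effects ICC and its tables.

The estimator is the classical ICC(1,1).  For a balanced panel of n
subjects measured in m sessions::

    MS_between = m * sum_i (ybar_i - ybar)^2 / (n - 1)
    MS_within  = sum_ij (y_ij - ybar_i)^2 / (n (m - 1))
    ICC_raw    = (MS_between - MS_within) / (MS_between + (m - 1) MS_within)

The between- and within-subject mean squares play the role of the
between- and within-subject variance components; the raw estimator can
be negative (theoretically uninterpretable reliability) and is clamped
to 0 for reporting, with the raw value kept for audit.  ICC values are
banded into five intervals: slight (0, 0.2], fair (0.2, 0.4], moderate
(0.4, 0.6], substantial (0.6, 0.8], almost perfect (0.8, 1.0]; an ICC of
exactly 0 is banded slight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .backbone import BackboneNetwork, build_backbone
from .metrics import (
    FIRST_ORDER,
    NullEnsembleConfig,
    global_metrics,
    nodal_efficiency,
    nodal_strength,
)
from .netbuild import Parcellation
from .richclub import classify_edges, classify_hubs
from .synthgen import TRTDataset

__all__ = [
    "MeasurementPanel",
    "ICCReport",
    "icc",
    "icc_array",
    "icc_band",
    "reliability_tables",
    "session_correlation",
    "gaussianize",
    "magnitude_vs_icc",
]

BANDS = ("slight", "fair", "moderate", "substantial", "almost perfect")
_BAND_EDGES = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class MeasurementPanel:
    """Subjects x sessions values for one quantity, plus grouping tags."""

    values: np.ndarray
    label: str = ""
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("panel must be a 2-D subjects x sessions array")
        if np.isnan(self.values).any():
            raise ValueError("panel has missing cells (balanced design required)")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValueError("panel needs >= 2 subjects and >= 2 sessions")


@dataclass
class ICCReport:
    label: str
    icc: float
    raw_icc: float
    ms_between: float
    ms_within: float
    band: str
    degenerate: bool = False
    tags: dict = field(default_factory=dict)


def icc_array(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ICC(1,1) over panels stacked in leading dimensions.

    ``values`` has shape (..., n, m).  Returns (icc, raw_icc, ms_between,
    ms_within); degenerate panels (both mean squares 0) get ICC 0.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape[-2:]
    if n < 2 or m < 2:
        raise ValueError("ICC needs >= 2 subjects and >= 2 sessions")
    subj_means = values.mean(axis=-1)
    grand = subj_means.mean(axis=-1, keepdims=True)
    ms_b = m * ((subj_means - grand) ** 2).sum(axis=-1) / (n - 1)
    ms_w = ((values - subj_means[..., None]) ** 2).sum(axis=(-2, -1)) / (n * (m - 1))
    denom = ms_b + (m - 1) * ms_w
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(denom > 0, (ms_b - ms_w) / np.where(denom > 0, denom, 1.0), 0.0)
    clamped = np.clip(raw, 0.0, None)
    return clamped, raw, ms_b, ms_w


def icc(panel: MeasurementPanel | np.ndarray) -> ICCReport:
    """ICC(1,1) for one balanced subjects x sessions panel."""
    if isinstance(panel, MeasurementPanel):
        values, label, tags = panel.values, panel.label, panel.tags
    else:
        values, label, tags = np.asarray(panel, dtype=float), "", {}
        MeasurementPanel(values)  # validate
    clamped, raw, ms_b, ms_w = icc_array(values)
    degenerate = bool(ms_b == 0 and ms_w == 0)
    val = float(clamped)
    return ICCReport(
        label=label,
        icc=val,
        raw_icc=float(raw),
        ms_between=float(ms_b),
        ms_within=float(ms_w),
        band=icc_band(val),
        degenerate=degenerate,
        tags=dict(tags),
    )


def icc_band(value: float) -> str:
    """Map an ICC in [0, 1] to its five-interval reliability band."""
    if not (0 <= value <= 1):
        raise ValueError(f"ICC {value} outside [0, 1]")
    if value == 0.0:
        return "slight"
    for edge, name in zip(_BAND_EDGES, BANDS):
        if value <= edge:
            return name
    return BANDS[-1]  # unreachable


def session_correlation(
    values_session1: np.ndarray, values_session2: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between the two sessions' value vectors.

    Returns (nan, nan) when either vector has zero variance (undefined).
    """
    x = np.asarray(values_session1, dtype=float)
    y = np.asarray(values_session2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("session vectors must have equal length")
    if x.size < 3:
        raise ValueError("session correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def gaussianize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom fractions.

    Maps value of rank r (average ranks on ties) to
    ``Phi^{-1}((r - 3/8) / (n + 1/4))``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("gaussianize needs n >= 3")
    ranks = sps.rankdata(values)
    return sps.norm.ppf((ranks - 0.375) / (values.size + 0.25))


def magnitude_vs_icc(
    mean_values: np.ndarray,
    icc_values: np.ndarray,
    gaussianize_first: bool = True,
) -> tuple[float, float]:
    """Correlation between group-mean magnitude and reliability.

    The magnitudes are optionally resampled into a Gaussian (rank
    inverse-normal) first, as is usual for heavy-tailed fiber counts.
    Returns (nan, nan) when the ICC vector is constant.
    """
    mags = np.asarray(mean_values, dtype=float)
    iccs = np.asarray(icc_values, dtype=float)
    if mags.shape != iccs.shape:
        raise ValueError("vectors must be aligned")
    if np.std(iccs) == 0 or np.std(mags) == 0:
        return float("nan"), float("nan")
    if gaussianize_first:
        mags = gaussianize(mags)
    return session_correlation(mags, iccs)


def _panel_from_arrays(arr: np.ndarray) -> np.ndarray:
    # arr: (n_subjects, n_sessions, ...) -> (..., n, m)
    return np.moveaxis(arr, (0, 1), (-2, -1))


def reliability_tables(
    dataset: TRTDataset,
    backbone: BackboneNetwork | None = None,
    metric_config: NullEnsembleConfig | None = None,
    parcellation: Parcellation | None = None,
    include_global: bool = True,
) -> dict[str, pd.DataFrame]:
    """ICC tables at the global, nodal and edge level.

    Global: one panel per global metric per network (null ensembles are
    seeded per subject x session off ``metric_config.seed``), tagged
    first/second order.  Nodal: strength and efficiency per node, tagged
    with the regional class (if a parcellation is given) and the hub flag
    derived from the backbone strengths.  Edge: backbone edge weights,
    tagged with the rich-club/feeder/local category; non-backbone edges
    are excluded.
    """
    if backbone is None:
        backbone = build_backbone(dataset)
    if metric_config is None:
        metric_config = NullEnsembleConfig()
    if dataset.node_labels != backbone.node_labels:
        raise ValueError("dataset and backbone must share the node set")
    n, m = dataset.n_subjects, dataset.n_sessions
    labels = dataset.node_labels
    n_nodes = len(labels)

    tables: dict[str, pd.DataFrame] = {}

    # ---- global level -------------------------------------------------
    if include_global:
        per_net = np.empty((n, m), dtype=object)
        root = np.random.SeedSequence(metric_config.seed)
        # one null-ensemble seed per subject, shared across sessions, so
        # identical sessions yield identical normalized metrics
        seeds = root.spawn(n)
        for i in range(n):
            cfg = NullEnsembleConfig(
                n_nulls=metric_config.n_nulls,
                swaps_per_edge=metric_config.swaps_per_edge,
                seed=int(seeds[i].generate_state(1)[0] % (2**31)),
            )
            for j in range(m):
                per_net[i, j] = global_metrics(dataset.matrices[i][j], cfg)
        rows = []
        for name in ("Sp", "Eglob", "Eloc", "Lp", "Cp", "lambda", "gamma", "sigma"):
            panel = np.array(
                [[per_net[i, j].as_dict()[name] for j in range(m)] for i in range(n)]
            )
            rep = icc(MeasurementPanel(panel, label=name))
            rows.append(
                {
                    "level": "global",
                    "label": name,
                    "icc": rep.icc,
                    "raw_icc": rep.raw_icc,
                    "band": rep.band,
                    "order_class": "first" if name in FIRST_ORDER else "second",
                    "mean_value": float(panel.mean()),
                }
            )
        tables["global"] = pd.DataFrame(rows)

    # ---- nodal level --------------------------------------------------
    arr = dataset.to_array()
    strengths = arr.sum(axis=-1)  # (n, m, N)
    effs = np.empty((n, m, n_nodes))
    for i in range(n):
        for j in range(m):
            effs[i, j] = nodal_efficiency(arr[i, j])
    backbone_strength = nodal_strength(backbone.mean_weights)
    hubs = classify_hubs(backbone_strength)
    rows = []
    for metric_name, data in (("nodal_strength", strengths), ("nodal_efficiency", effs)):
        panels = _panel_from_arrays(data)  # (N, n, m)
        iccs, raws, _, _ = icc_array(panels)
        for k, lab in enumerate(labels):
            rows.append(
                {
                    "level": "nodal",
                    "label": lab,
                    "metric": metric_name,
                    "icc": float(iccs[k]),
                    "raw_icc": float(raws[k]),
                    "band": icc_band(float(iccs[k])),
                    "regional_class": (
                        parcellation.node_class.get(lab) if parcellation else None
                    ),
                    "hub": bool(hubs[k]),
                    "mean_value": float(data[:, :, k].mean()),
                }
            )
    tables["nodal"] = pd.DataFrame(rows)

    # ---- edge level ---------------------------------------------------
    cats = classify_edges(backbone.mean_weights, hubs)
    iu, ju = np.nonzero(np.triu(backbone.survived, 1))
    panels = _panel_from_arrays(arr[:, :, iu, ju])  # (E, n, m)
    iccs, raws, _, _ = icc_array(panels)
    rows = []
    for e in range(len(iu)):
        i, j = iu[e], ju[e]
        rows.append(
            {
                "level": "edge",
                "label": f"{labels[i]}--{labels[j]}",
                "icc": float(iccs[e]),
                "raw_icc": float(raws[e]),
                "band": icc_band(float(iccs[e])),
                "edge_category": cats[i, j],
                "mean_value": float(arr[:, :, i, j].mean()),
            }
        )
    tables["edge"] = pd.DataFrame(rows)
    return tables
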