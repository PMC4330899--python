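"""End-to-end synthetic test-retest reliability run.

``run_pipeline`` executes the full analysis sequence — generate (or load)
a subjects x sessions connectome dataset, extract the sign-test backbone,
profile rich-club organization, compute global/nodal/edge ICC tables,
magnitude-vs-reliability correlations and the binary-vs-weighted paired
comparison — and writes every artifact plus a checksum manifest, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as crio
from .backbone import build_backbone
from .metrics import NullEnsembleConfig
from .netbuild import ConnectomeMatrix, Parcellation, binarize
from .reliability import (
    MeasurementPanel,
    icc,
    magnitude_vs_icc,
    reliability_tables,
)
from .richclub import normalized_rich_club
from .stats import paired_ttest
from .synthgen import (
    TRTConfig,
    TRTDataset,
    make_template,
    simulate_trt,
    subdivide_template,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    # synthetic scenario
    n_nodes: int = 80
    target_density: float = 0.2
    core_fraction: float = 0.15
    weight_scale: float = 50.0
    resolution: str = "low"          # "low" or "high" (subdivide by `factor`)
    factor: int = 13
    concentration: float = 0.035
    n_subjects: int = 11
    n_sessions: int = 2
    sigma_bs2: float = 0.04
    sigma_ws2: float = 100.0
    noise_model: str = "gaussian_additive"
    variance_mode: str = "mixed"
    dropout_prob: float = 0.0
    # analysis
    n_nulls: int = 100
    swaps_per_edge: int = 10
    backbone_alpha: float = 0.05
    session_rule: str = "either"
    richclub_k: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    include_binary_global: bool = True
    # bookkeeping
    seed: int = 0
    scenario_tag: str = "default"

    def __post_init__(self) -> None:
        if self.resolution not in ("low", "high"):
            raise ValueError("resolution must be 'low' or 'high'")
        self.richclub_k = tuple(float(k) for k in self.richclub_k)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _global_icc_table(dataset: TRTDataset, cfg: NullEnsembleConfig) -> pd.DataFrame:
    tables = reliability_tables(dataset, metric_config=cfg)
    return tables["global"]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the whole analysis and return a manifest dict (also written).

    Stages: synthgen -> backbone -> richclub -> reliability (global /
    nodal / edge) -> magnitude-vs-ICC + category summaries -> stats.
    """
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- synthgen -----------------------------------------------------
    template = make_template(
        config.n_nodes,
        config.target_density,
        config.core_fraction,
        config.weight_scale,
        seed=config.seed,
    )
    node_map = None
    if config.resolution == "high":
        template, node_map = subdivide_template(
            template, config.factor, seed=config.seed, concentration=config.concentration
        )
    trt_cfg = TRTConfig(
        n_subjects=config.n_subjects,
        n_sessions=config.n_sessions,
        sigma_bs2=config.sigma_bs2,
        sigma_ws2=config.sigma_ws2,
        noise_model=config.noise_model,
        variance_mode=config.variance_mode,
        dropout_prob=config.dropout_prob,
        seed=config.seed,
    )
    dataset = simulate_trt(template, trt_cfg)
    logger.info(
        "pipeline[%s]: simulated %d subjects x %d sessions, %d nodes (%.1fs)",
        config.scenario_tag,
        dataset.n_subjects,
        dataset.n_sessions,
        len(dataset.node_labels),
        time.monotonic() - t0,
    )
    crio.write_dataset(dataset, outdir / "dataset")
    parcellation = Parcellation(
        list(template.node_labels),
        dict(template.node_class),
        low_res_group=node_map,
    )
    crio.write_parcellation(
        parcellation,
        outdir / "nodes.tsv",
        core_flag={
            lab: bool(template.core_flag[k])
            for k, lab in enumerate(template.node_labels)
        },
    )

    # ---- backbone -----------------------------------------------------
    backbone = build_backbone(
        dataset, alpha=config.backbone_alpha, session_rule=config.session_rule
    )
    crio.write_matrix(
        ConnectomeMatrix(backbone.node_labels, backbone.mean_weights),
        outdir / "backbone.tsv",
    )
    backbone.edge_table().to_csv(
        outdir / "backbone_edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # ---- rich club ----------------------------------------------------
    null_cfg = NullEnsembleConfig(
        n_nulls=config.n_nulls,
        swaps_per_edge=config.swaps_per_edge,
        seed=config.seed + 1,
    )
    profile = normalized_rich_club(
        backbone.mean_weights, k_values=config.richclub_k, null_config=null_cfg
    )
    profile.to_frame().to_csv(
        outdir / "richclub.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # ---- reliability --------------------------------------------------
    metric_cfg = NullEnsembleConfig(
        n_nulls=config.n_nulls,
        swaps_per_edge=config.swaps_per_edge,
        seed=config.seed + 2,
    )
    tables = reliability_tables(
        dataset, backbone, metric_config=metric_cfg, parcellation=parcellation
    )
    for level, df in tables.items():
        df.to_csv(
            outdir / f"icc_{level}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
    logger.info(
        "pipeline[%s]: reliability tables done (%.1fs)",
        config.scenario_tag,
        time.monotonic() - t0,
    )

    # ---- summaries + stats --------------------------------------------
    nodal = tables["nodal"]
    edge = tables["edge"]
    strength_rows = nodal[nodal["metric"] == "nodal_strength"]
    r_node, p_node = magnitude_vs_icc(
        strength_rows["mean_value"].to_numpy(), strength_rows["icc"].to_numpy()
    )
    r_edge, p_edge = magnitude_vs_icc(
        edge["mean_value"].to_numpy(), edge["icc"].to_numpy()
    )
    cat_means = (
        edge.groupby("edge_category")["icc"].mean().to_dict()
        if len(edge)
        else {}
    )
    hub_means = strength_rows.groupby("hub")["icc"].mean()

    summary = {
        "scenario": config.scenario_tag,
        "n_nodes": len(dataset.node_labels),
        "sparsity_mean": float(
            np.mean(
                [
                    np.count_nonzero(np.triu(m.weights, 1))
                    / (m.n_nodes * (m.n_nodes - 1) / 2)
                    for row in dataset.matrices
                    for m in row
                ]
            )
        ),
        "backbone_n_edges": backbone.n_edges,
        "magnitude_vs_icc": {
            "nodal_strength_r": r_node,
            "nodal_strength_p": p_node,
            "edge_weight_r": r_edge,
            "edge_weight_p": p_edge,
        },
        "edge_icc_by_category": {k: float(v) for k, v in cat_means.items()},
        "nodal_strength_icc_hub": float(hub_means.get(True, float("nan"))),
        "nodal_strength_icc_nonhub": float(hub_means.get(False, float("nan"))),
        "mean_edge_icc": float(edge["icc"].mean()) if len(edge) else float("nan"),
        "global_icc": dict(zip(tables["global"]["label"], tables["global"]["icc"])),
    }

    if config.include_binary_global:
        bin_dataset = TRTDataset(
            dataset.node_labels,
            [[binarize(m) for m in row] for row in dataset.matrices],
            provenance={"derived": "binarized"},
        )
        bin_global = _global_icc_table(bin_dataset, metric_cfg)
        bin_global.to_csv(
            outdir / "icc_global_binary.tsv",
            sep="\t",
            index=False,
            float_format=_FLOAT_FMT,
        )
        tt = paired_ttest(
            tables["global"]["icc"].to_numpy(), bin_global["icc"].to_numpy()
        )
        summary["binary_vs_weighted"] = {
            "t": tt.t,
            "p": tt.p,
            "mean_icc_weighted": float(tables["global"]["icc"].mean()),
            "mean_icc_binary": float(bin_global["icc"].mean()),
            "zero_variance": tt.zero_variance,
        }

    _write_json(summary, outdir / "summary.json")

    # ---- manifest with content checksums ------------------------------
    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "run_manifest.json"
    )
    manifest = {
        "config": asdict(config),
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    _write_json(manifest, outdir / "run_manifest.json")
    logger.info(
        "pipeline[%s]: finished in %.1fs", config.scenario_tag, time.monotonic() - t0
    )
    return manifest
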