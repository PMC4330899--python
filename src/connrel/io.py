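"""Plain-text readers/writers: TSV matrices, endpoint tables, node metadata,
and the ``sub-<i>/ses-<j>/connectome.tsv`` dataset tree."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .netbuild import ConnectomeMatrix, Parcellation, StreamlineEndpointTable
from .synthgen import TRTDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_endpoints",
    "write_endpoints",
    "read_parcellation",
    "write_parcellation",
    "read_dataset",
    "write_dataset",
]

_FLOAT_FMT = "%.12g"


def write_matrix(matrix: ConnectomeMatrix, path: str | Path) -> None:
    """Square TSV: first row and column hold node labels."""
    df = pd.DataFrame(
        matrix.weights, index=matrix.node_labels, columns=matrix.node_labels
    )
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="label")


def read_matrix(path: str | Path, resolution_tag: str = "low") -> ConnectomeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    w = df.to_numpy(dtype=float)
    if np.isnan(w).any():
        i, j = np.argwhere(np.isnan(w))[0]
        raise ValueError(f"{path}: NaN cell at ({df.index[i]}, {df.columns[j]})")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise ValueError(f"{path}: negative weight at ({df.index[i]}, {df.columns[j]})")
    if not np.allclose(w, w.T):
        i, j = np.argwhere(~np.isclose(w, w.T))[0]
        raise ValueError(f"{path}: asymmetric at ({df.index[i]}, {df.columns[j]})")
    return ConnectomeMatrix([str(x) for x in df.index], w, resolution_tag)


def write_endpoints(table: StreamlineEndpointTable, path: str | Path) -> None:
    pd.DataFrame(table.records, columns=["label_a", "label_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_endpoints(path: str | Path) -> StreamlineEndpointTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return StreamlineEndpointTable(
        [(a, b) for a, b in zip(df["label_a"], df["label_b"])]
    )


def write_parcellation(
    parcellation: Parcellation, path: str | Path, core_flag: dict | None = None
) -> None:
    rows = []
    for lab in parcellation.labels:
        rows.append(
            {
                "label": lab,
                "node_class": parcellation.node_class.get(lab, ""),
                "core_flag": int(core_flag.get(lab, 0)) if core_flag else "",
                "low_res_group": (
                    parcellation.low_res_group.get(lab, "")
                    if parcellation.low_res_group
                    else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_parcellation(path: str | Path) -> Parcellation:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    labels = list(df["label"])
    node_class = {
        r["label"]: r["node_class"] for _, r in df.iterrows() if r["node_class"]
    }
    low = None
    if "low_res_group" in df.columns and df["low_res_group"].any():
        low = {r["label"]: r["low_res_group"] for _, r in df.iterrows()}
    return Parcellation(labels, node_class, low)


def write_dataset(dataset: TRTDataset, outdir: str | Path) -> None:
    """Directory tree ``sub-<i>/ses-<j>/connectome.tsv`` plus manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, row in enumerate(dataset.matrices, start=1):
        for j, mat in enumerate(row, start=1):
            d = outdir / f"sub-{i}" / f"ses-{j}"
            d.mkdir(parents=True, exist_ok=True)
            write_matrix(mat, d / "connectome.tsv")
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "n_subjects": dataset.n_subjects,
                "n_sessions": dataset.n_sessions,
                "node_labels": dataset.node_labels,
                "provenance": dataset.provenance,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def read_dataset(indir: str | Path) -> TRTDataset:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    matrices = []
    for i in range(1, manifest["n_subjects"] + 1):
        row = []
        for j in range(1, manifest["n_sessions"] + 1):
            row.append(read_matrix(indir / f"sub-{i}" / f"ses-{j}" / "connectome.tsv"))
        matrices.append(row)
    return TRTDataset(
        manifest["node_labels"], matrices, provenance=manifest.get("provenance", {})
    )
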