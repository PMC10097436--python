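"""Delimited-text I/O for response matrices, designs and networks.

Canonical dialect: TSV with a header row of experiment (or node) labels
and a first column of node names, UTF-8, decimal point.  Designs are
3/4-column TSV (experiment, target_node, intensity[, replicate]) or the
equivalent JSON.  Networks can be written as a full matrix, as a signed
edge list of the nonzero off-diagonal coefficients, or as JSON with a
manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, GlobalResponseMatrix, PerturbationDesign

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_design",
    "write_design",
    "read_network",
    "write_network",
    "read_prior_null",
]


def _read_matrix_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate experiment labels {dupes}")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = [
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
            for i, j in zip(*np.where(body.isna().to_numpy()))
        ]
        raise ValueError(f"{path}: non-numeric cells at {bad[:5]}")
    return body


def read_design(path) -> pd.DataFrame:
    """Read a perturbation design table (TSV or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"experiment", "target_node", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: design needs columns {sorted(required)}")
    return df


def write_design(design: PerturbationDesign, path, node_names=None) -> None:
    design.to_frame(node_names).to_csv(path, sep="\t", index=False)


def read_response_matrix(path, design_path) -> GlobalResponseMatrix:
    """Read a nodes x experiments TSV plus its design descriptor.

    The design's ``experiment`` column must cover every matrix column
    and its ``target_node`` values must name matrix rows.
    """
    body = _read_matrix_frame(path)
    design = read_design(design_path)
    missing = set(map(str, body.columns)) - set(map(str, design["experiment"]))
    if missing:
        raise ValueError(f"{design_path}: no design row for experiments {sorted(missing)}")
    design = design.set_index("experiment").loc[[str(c) for c in body.columns]]
    node_names = [str(i) for i in body.index]
    unknown = set(map(str, design["target_node"])) - set(node_names)
    if unknown:
        raise ValueError(f"{design_path}: unknown target nodes {sorted(unknown)}")
    reps = (
        design["replicate"].to_numpy(int) - 1
        if "replicate" in design.columns
        else None
    )
    pdesign = PerturbationDesign(
        np.array([node_names.index(str(t)) for t in design["target_node"]]),
        design["intensity"].to_numpy(float),
        reps,
        experiment_names=[str(c) for c in body.columns],
    )
    return GlobalResponseMatrix(body.to_numpy(float), pdesign, node_names)


def write_response_matrix(R: GlobalResponseMatrix, path, design_path=None) -> None:
    R.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    if design_path is not None:
        R.design.to_frame(R.node_names).to_csv(design_path, sep="\t", index=False)


def read_network(path) -> ConnectivityMatrix:
    """Read a connectivity matrix from TSV (matrix or edge-list layout).

    Edge lists need columns (source, target, coefficient) plus a header
    comment line ``# nodes: a,b,c`` fixing the node order.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if first.startswith("# nodes:"):
        names = [s.strip() for s in first.split(":", 1)[1].split(",")]
        edges = pd.read_csv(path, sep="\t", comment="#")
        values = np.zeros((len(names), len(names)))
        np.fill_diagonal(values, -1.0)
        for _, row in edges.iterrows():
            i = names.index(str(row["target"]))
            j = names.index(str(row["source"]))
            values[i, j] = float(row["coefficient"])
        return ConnectivityMatrix(values, names)
    body = _read_matrix_frame(path)
    return ConnectivityMatrix(
        body.to_numpy(float), [str(i) for i in body.index]
    )


def write_network(r: ConnectivityMatrix, path, format: str = "matrix_tsv") -> None:
    """Write a network as ``matrix_tsv``, ``edge_list_tsv`` or ``json``."""
    path = Path(path)
    if format == "matrix_tsv":
        r.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    elif format == "edge_list_tsv":
        names = r.node_names
        lines = ["# nodes: " + ",".join(names), "source\ttarget\tcoefficient"]
        for i in range(r.n_nodes):
            for j in range(r.n_nodes):
                if i != j and r.values[i, j] != 0.0:
                    lines.append(f"{names[j]}\t{names[i]}\t{r.values[i, j]:.17g}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        path.write_text(
            json.dumps(
                {"nodes": r.node_names, "values": r.values.tolist()}, indent=1
            )
        )
    else:
        raise ValueError("format must be matrix_tsv, edge_list_tsv or json")


def read_prior_null(path, node_names: list[str]) -> dict[int, set[int]]:
    """Read known-null edges from a 2-column TSV (target_node, null_source)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    prior: dict[int, set[int]] = {}
    for _, row in df.iterrows():
        tgt, src = str(row[cols[0]]), str(row[cols[1]])
        for name in (tgt, src):
            if name not in node_names:
                raise ValueError(f"{path}: unknown node {name!r}")
        prior.setdefault(node_names.index(tgt), set()).add(node_names.index(src))
    return prior
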