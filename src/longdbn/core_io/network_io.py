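"""Network export/import: TSV (lossless round trip), GraphML and SIF."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .types import SLICE_T, SLICE_T1, DBNModel, Edge, NodeRef

_TSV_COLUMNS = ["parent_layer", "parent_feature", "child_layer",
                "child_feature", "lag", "coefficient", "normalized_weight",
                "bootstrap_support"]


def _edge_records(edges: list[Edge]) -> pd.DataFrame:
    rows = [
        {"parent_layer": e.parent.kind, "parent_feature": e.parent.feature,
         "child_layer": e.child.kind, "child_feature": e.child.feature,
         "lag": e.lag, "coefficient": e.coefficient,
         "normalized_weight": e.normalized_weight,
         "bootstrap_support": e.bootstrap_support}
        for e in sorted(edges, key=lambda e: e.key)
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def export_network(model: DBNModel, path: str | Path, format: str = "tsv") -> Path:
    """Serialize a model's edges (with sign, lag, support) to ``path``."""
    path = Path(path)
    if format == "tsv":
        _edge_records(model.edges).to_csv(path, sep="\t", index=False,
                                          float_format="%.12g")
    elif format == "graphml":
        g = nx.DiGraph()
        for node in sorted(model.nodes):
            g.add_node(str(node), kind=node.kind, feature=node.feature,
                       slice=node.slice_)
        for e in sorted(model.edges, key=lambda e: e.key):
            g.add_edge(str(e.parent), str(e.child), lag=e.lag,
                       coefficient=float(e.coefficient),
                       normalized_weight=float(e.normalized_weight),
                       bootstrap_support=float(e.bootstrap_support))
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for e in sorted(model.edges, key=lambda e: e.key):
                fh.write(f"{e.parent.kind}:{e.parent.feature}\t{e.lag}\t"
                         f"{e.child.kind}:{e.child.feature}\n")
            for node in sorted(model.nodes):
                fh.write(f"{node.kind}:{node.feature}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def read_network_tsv(path: str | Path) -> list[Edge]:
    """Inverse of the TSV export; reproduces the edge set exactly."""
    tab = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    edges = []
    for rec in tab.itertuples(index=False):
        child = NodeRef(rec.child_layer, str(rec.child_feature), SLICE_T1)
        parent_slice = SLICE_T if rec.lag == "inter" else SLICE_T1
        parent = NodeRef(rec.parent_layer, str(rec.parent_feature), parent_slice)
        edges.append(Edge(parent, child, rec.lag,
                          coefficient=float(rec.coefficient),
                          normalized_weight=float(rec.normalized_weight),
                          bootstrap_support=float(rec.bootstrap_support)))
    return edges
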