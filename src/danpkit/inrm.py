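"""Influential network relation maps (INRM).

An INRM positions every factor at ``(x, y) = (center, net)`` — overall
involvement on the horizontal axis, net cause/effect on the vertical — and
draws a directed arrow i -> j for every influence ``t_ij`` at or above a
threshold.  Factors above the horizontal axis (net > 0) form the cause group,
the sources of influence a decision-maker should act on; factors at or below
it form the effect group.

The dimension-level map is built from T_D; criteria-level maps are built per
dimension from the within-dimension diagonal blocks of T, which is the
conventional presentation of the map.  The edge threshold defaults to the mean
of the off-diagonal entries of the matrix in use — the most common DEMATEL
convention — and must be overridden explicitly to reproduce maps drawn with a
different cutoff.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .factor_model import FactorSystem

__all__ = [
    "build_inrm",
    "build_inrm_maps",
    "export_inrm",
    "import_inrm_csv",
    "resolve_threshold",
]


def resolve_threshold(T: np.ndarray, rule: str | float = "mean") -> float:
    """Turn a threshold rule into a numeric cutoff.

    ``"mean"`` (default) is the mean of the off-diagonal entries of ``T``; a
    number (or ``"value:<x>"`` string) is used verbatim.
    """
    if isinstance(rule, str):
        if rule == "mean":
            T = np.asarray(T, dtype=float)
            off = ~np.eye(T.shape[0], dtype=bool)
            return float(T[off].mean())
        if rule.startswith("value:"):
            return float(rule.split(":", 1)[1])
        raise ValueError(f"unknown threshold rule {rule!r}")
    return float(rule)


def build_inrm(
    indices: pd.DataFrame,
    T: np.ndarray,
    threshold: str | float = "mean",
    level: str = "criterion",
) -> nx.DiGraph:
    """Build the INRM graph for one set of factors.

    ``indices`` must carry ``center``, ``net`` and ``group`` rows for exactly
    the factors of ``T`` (as produced by
    :func:`danpkit.dematel.influence_indices`).  Nodes get attributes
    ``x`` (center), ``y`` (net), ``group`` and ``level``; a directed edge
    i -> j with attribute ``strength`` = ``t_ij`` is kept when ``t_ij`` is at
    least the threshold.  If the threshold excludes every edge a warning is
    emitted and the node-only graph returned.
    """
    T = np.asarray(T, dtype=float)
    labels = list(indices.index)
    if T.shape != (len(labels), len(labels)):
        raise ValueError(f"index table has {len(labels)} factors but T is {T.shape}")
    cutoff = resolve_threshold(T, threshold)
    graph = nx.DiGraph(threshold=cutoff, level=level)
    for label, row in indices.iterrows():
        graph.add_node(
            label,
            x=float(row["center"]),
            y=float(row["net"]),
            group=str(row["group"]),
            level=level,
        )
    for i, src in enumerate(labels):
        for j, tgt in enumerate(labels):
            if i != j and T[i, j] >= cutoff:
                graph.add_edge(src, tgt, strength=float(T[i, j]))
    if graph.number_of_edges() == 0:
        warnings.warn(
            f"threshold {cutoff:.6g} excludes every edge of the {level}-level map",
            stacklevel=2,
        )
    return graph


def build_inrm_maps(
    system: FactorSystem,
    criteria_indices: pd.DataFrame,
    dimension_indices: pd.DataFrame,
    T: np.ndarray,
    T_D: np.ndarray,
    threshold: str | float = "mean",
) -> dict[str, nx.DiGraph]:
    """One dimension-level map plus one criteria-level map per dimension.

    Keys: ``"dimensions"`` for the T_D map, and each dimension code for the map
    over its own criteria (the diagonal block of T).  A numeric threshold
    applies to every map; the ``"mean"`` rule is evaluated per matrix.
    """
    maps = {"dimensions": build_inrm(dimension_indices, T_D, threshold, level="dimension")}
    for dim, block in zip(system.dimensions, system.block_slices()):
        codes = [c.code for c in dim.criteria]
        maps[dim.code] = build_inrm(
            criteria_indices.loc[codes], np.asarray(T)[block, block], threshold, level="criterion"
        )
    return maps


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_NODE_FIELDS = ("code", "level", "x", "y", "group")
_EDGE_FIELDS = ("source", "target", "strength")


def export_inrm(graph: nx.DiGraph, fmt: str, path: str | Path) -> list[Path]:
    """Write an INRM graph as ``dot``, ``graphml`` or ``csv``; returns paths written.

    DOT and GraphML carry x/y/group/level as node attributes (positive y is the
    cause half-plane); CSV writes ``<path>/nodes.csv`` and ``<path>/edges.csv``
    and is lossless under :func:`import_inrm_csv`.
    """
    path = Path(path)
    if fmt == "dot":
        lines = ["digraph INRM {"]
        for node, attrs in graph.nodes(data=True):
            lines.append(
                f'  "{node}" [x={attrs["x"]!r}, y={attrs["y"]!r}, '
                f'group="{attrs["group"]}", level="{attrs["level"]}", '
                f'pos="{attrs["x"]!r},{attrs["y"]!r}!"];'
            )
        for src, tgt, attrs in graph.edges(data=True):
            lines.append(f'  "{src}" -> "{tgt}" [strength={attrs["strength"]!r}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return [path]
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return [path]
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        nodes_path, edges_path = path / "nodes.csv", path / "edges.csv"
        with open(nodes_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_NODE_FIELDS)
            for node, attrs in graph.nodes(data=True):
                writer.writerow([node, attrs["level"], repr(attrs["x"]), repr(attrs["y"]), attrs["group"]])
        with open(edges_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_EDGE_FIELDS)
            for src, tgt, attrs in graph.edges(data=True):
                writer.writerow([src, tgt, repr(attrs["strength"])])
        return [nodes_path, edges_path]
    raise ValueError(f"unknown INRM export format {fmt!r}")


def import_inrm_csv(path: str | Path) -> nx.DiGraph:
    """Rebuild an INRM graph from a ``nodes.csv`` / ``edges.csv`` directory."""
    path = Path(path)
    graph = nx.DiGraph()
    with open(path / "nodes.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            graph.add_node(
                row["code"],
                x=float(row["x"]),
                y=float(row["y"]),
                group=row["group"],
                level=row["level"],
            )
    with open(path / "edges.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            graph.add_edge(row["source"], row["target"], strength=float(row["strength"]))
    return graph
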