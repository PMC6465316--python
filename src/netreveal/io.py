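"""Graph readers/writers and preprocessing.

Every loader coerces its input to an undirected simple graph: self-loops
are dropped (with a logged count), duplicate and reversed edge lines are
collapsed, and weights are binarized.  All model components assume simple
undirected graphs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_adjacency_csv",
    "read_interaction_table",
    "largest_connected_component",
    "write_graphml",
]


def read_edge_list(
    path,
    delimiter: Optional[str] = None,
    comment: str = "#",
) -> nx.Graph:
    """Read a SNAP-style edge list (whitespace/tab/comma separated).

    Node labels are kept verbatim as strings.  Duplicate and reversed
    lines collapse to a single undirected edge; self-loop lines are
    dropped and counted.
    """
    G = nx.Graph()
    loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment):
                continue
            if delimiter is None:
                parts = line.replace(",", " ").split()
            else:
                parts = [p for p in line.split(delimiter) if p != ""]
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {lineno}: {raw!r}")
            u, v = parts[0], parts[1]
            if u == v:
                loops += 1
                continue
            G.add_edge(u, v)
    if loops:
        logger.info("read_edge_list(%s): dropped %d self-loop line(s)", path, loops)
    return G


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write a whitespace-delimited edge list (one undirected edge per line)."""
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u} {v}\n")


def read_adjacency_csv(path) -> nx.Graph:
    """Read a labeled square adjacency matrix (connectome-style CSV).

    An undirected edge is present iff either of the two symmetric entries
    is positive (OR rule); weights are discarded and the diagonal ignored.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: adjacency matrix must be square, got {df.shape}"
        )
    labels = [str(x) for x in df.index]
    G = nx.Graph()
    G.add_nodes_from(labels)
    vals = df.to_numpy()
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if vals[i, j] > 0 or vals[j, i] > 0:
                G.add_edge(labels[i], labels[j])
    return G


def read_interaction_table(
    path,
    id_columns: tuple[int, int] = (0, 1),
    delimiter: str = "\t",
    skip_header: bool = True,
) -> nx.Graph:
    """Read a tab-delimited interaction table (two id columns, rest ignored)."""
    G = nx.Graph()
    loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            try:
                u = parts[id_columns[0]].strip()
                v = parts[id_columns[1]].strip()
            except IndexError as exc:
                raise ValueError(f"{path}: malformed line {lineno}") from exc
            if u == v:
                loops += 1
                continue
            G.add_edge(u, v)
    if loops:
        logger.info(
            "read_interaction_table(%s): dropped %d self-interaction(s)", path, loops
        )
    return G


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component.

    Size ties break toward the component containing the smallest node
    label (string order), so the choice is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    comps = list(nx.connected_components(graph))
    comps.sort(key=lambda c: (-len(c), min(str(u) for u in c)))
    return graph.subgraph(comps[0]).copy()


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export for visualization tools."""
    out = nx.relabel_nodes(graph, {u: str(u) for u in graph.nodes()}, copy=True)
    nx.write_graphml(out, Path(path))
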