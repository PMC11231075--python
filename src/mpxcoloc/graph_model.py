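"""Bipartite cell graphs from Molecular Pixelation (MPX) and their A-node projections.

An MPX cell is a bipartite graph whose two node sets are A-pixels and
B-pixels (DNA-tagged spatial neighborhoods) and whose edges are antibody
molecules, labeled with the target marker and an unique-molecule count.
Downstream scoring works on the *A-node projection*: two A-pixels are
adjacent iff they share at least one B-pixel, and the marker counts move
from edges onto the incident A-node, so each vertex carries a count
vector over the antibody panel.

Cells are exchanged as plain delimited edge-list tables with columns
``cell_id, upia, upib, marker, count`` (comma- or tab-separated, chosen
by file extension), together with a panel manifest table with columns
``marker, is_isotype``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_LIST_COLUMNS = ("cell_id", "upia", "upib", "marker", "count")

_TRUE_STRINGS = {"true", "t", "yes", "1"}
_FALSE_STRINGS = {"false", "f", "no", "0"}


def _delimiter_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


@dataclass(frozen=True)
class PanelManifest:
    """Antibody panel: ordered marker names plus the isotype-control subset.

    Isotype controls are antibodies with no specific target; their counts
    set a per-cell noise floor used to filter low-information markers.
    """

    markers: tuple[str, ...]
    isotype_markers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        if len(set(markers)) != len(markers):
            dupes = sorted({m for m in markers if markers.count(m) > 1})
            raise ValueError(f"duplicate marker names in panel: {dupes}")
        object.__setattr__(self, "markers", markers)
        iso = frozenset(self.isotype_markers)
        unknown = iso - set(markers)
        if unknown:
            raise ValueError(f"isotype markers not in panel: {sorted(unknown)}")
        object.__setattr__(self, "isotype_markers", iso)

    @property
    def specific_markers(self) -> tuple[str, ...]:
        """Markers that are not isotype controls, in panel order."""
        return tuple(m for m in self.markers if m not in self.isotype_markers)

    @classmethod
    def from_table(cls, path: str | Path) -> "PanelManifest":
        """Read a panel manifest table with columns marker, is_isotype."""
        df = pd.read_csv(path, sep=_delimiter_for(path), comment="#", dtype=str)
        missing = {"marker", "is_isotype"} - set(df.columns)
        if missing:
            raise ValueError(f"panel manifest {path} missing columns: {sorted(missing)}")
        iso: set[str] = set()
        for _, row in df.iterrows():
            flag = str(row["is_isotype"]).strip().lower()
            if flag in _TRUE_STRINGS:
                iso.add(row["marker"])
            elif flag not in _FALSE_STRINGS:
                raise ValueError(
                    f"unrecognized is_isotype value {row['is_isotype']!r} "
                    f"for marker {row['marker']!r}"
                )
        return cls(markers=tuple(df["marker"]), isotype_markers=frozenset(iso))

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "marker": self.markers,
                "is_isotype": [m in self.isotype_markers for m in self.markers],
            }
        ).to_csv(path, sep=_delimiter_for(path), index=False)


@dataclass
class BipartiteCellGraph:
    """One cell's bipartite pixel graph.

    ``edges`` maps ``(a_id, b_id, marker)`` to a positive molecule count;
    rows that repeat the same key are summed on construction by the
    reader.
    """

    cell_id: str
    a_nodes: set[str]
    b_nodes: set[str]
    edges: dict[tuple[str, str, str], int]

    def __post_init__(self) -> None:
        overlap = self.a_nodes & self.b_nodes
        if overlap:
            raise ValueError(f"pixel ids on both sides of the bipartition: {sorted(overlap)[:5]}")
        for (a, b, marker), count in self.edges.items():
            if a not in self.a_nodes or b not in self.b_nodes:
                raise ValueError(f"edge ({a}, {b}, {marker}) has an endpoint outside the node sets")
            if count < 1:
                raise ValueError(f"edge ({a}, {b}, {marker}) has non-positive count {count}")

    @property
    def markers(self) -> set[str]:
        return {m for (_, _, m) in self.edges}

    def marker_totals(self) -> dict[str, int]:
        """Total molecule count per marker in this cell."""
        totals: dict[str, int] = {}
        for (_, _, marker), count in self.edges.items():
            totals[marker] = totals.get(marker, 0) + count
        return totals

    def total_count(self) -> int:
        return sum(self.edges.values())


@dataclass
class AnodeGraph:
    """A-node projection of a bipartite cell graph.

    ``graph`` is a simple undirected networkx graph on A-pixel ids;
    ``node_counts`` is a nodes x markers integer DataFrame whose row
    order defines the node order used by all score vectors.
    """

    cell_id: str
    graph: nx.Graph
    node_counts: pd.DataFrame

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.node_counts.index)

    @property
    def n_nodes(self) -> int:
        return len(self.node_counts)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.node_counts.columns)

    def marker_vector(self, marker: str) -> np.ndarray:
        """Counts of one marker over nodes, in node order."""
        return self.node_counts[marker].to_numpy(dtype=float)

    def degrees(self) -> np.ndarray:
        d = dict(self.graph.degree())
        return np.array([d[v] for v in self.nodes], dtype=float)

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)


def read_cell_edge_list(
    table_path: str | Path, panel: PanelManifest
) -> list[BipartiteCellGraph]:
    """Read a delimited edge-list table into one graph per cell.

    Rows sharing ``(cell_id, upia, upib, marker)`` have their counts
    summed. Markers absent from the panel, non-positive counts and
    missing columns are hard errors.
    """
    df = pd.read_csv(
        table_path,
        sep=_delimiter_for(table_path),
        comment="#",
        dtype={"cell_id": str, "upia": str, "upib": str, "marker": str},
    )
    missing = set(EDGE_LIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edge list {table_path} missing columns: {sorted(missing)}")
    if df.empty:
        return []
    unknown = set(df["marker"]) - set(panel.markers)
    if unknown:
        raise ValueError(f"markers not in panel: {sorted(unknown)}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts <= 0) | (counts != counts.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"invalid count {df['count'].iloc[row]!r} at data row {row + 1} "
            f"(counts must be positive integers)"
        )
    df = df.assign(count=counts.astype(int))
    agg = (
        df.groupby(["cell_id", "upia", "upib", "marker"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    cells: list[BipartiteCellGraph] = []
    for cell_id, sub in agg.groupby("cell_id", sort=True):
        edges = {
            (r.upia, r.upib, r.marker): int(r.count)
            for r in sub.itertuples(index=False)
        }
        cells.append(
            BipartiteCellGraph(
                cell_id=str(cell_id),
                a_nodes=set(sub["upia"]),
                b_nodes=set(sub["upib"]),
                edges=edges,
            )
        )
    return cells


def write_cell_edge_list(
    cells: Iterable[BipartiteCellGraph], path: str | Path, header_comment: str | None = None
) -> None:
    """Write cells back to the delimited edge-list dialect."""
    rows = []
    for cell in cells:
        for (a, b, marker), count in sorted(cell.edges.items()):
            rows.append((cell.cell_id, a, b, marker, count))
    df = pd.DataFrame(rows, columns=list(EDGE_LIST_COLUMNS))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=_delimiter_for(path), index=False)


def project_to_anodes(
    g: BipartiteCellGraph, panel: PanelManifest | None = None
) -> AnodeGraph:
    """Project a bipartite cell graph onto its A-nodes.

    Two A-pixels become adjacent iff they share at least one B-pixel
    (simple, unweighted adjacency); per-marker edge counts are summed
    onto the incident A-node, so per-marker totals are conserved.
    A-pixels with no incident edge are retained as isolated nodes.
    """
    markers = panel.markers if panel is not None else tuple(sorted(g.markers))
    nodes = sorted(g.a_nodes)
    node_index = {v: i for i, v in enumerate(nodes)}
    counts = np.zeros((len(nodes), len(markers)), dtype=np.int64)
    marker_index = {m: j for j, m in enumerate(markers)}
    b_neighbors: dict[str, set[str]] = {}
    for (a, b, marker), count in g.edges.items():
        b_neighbors.setdefault(b, set()).add(a)
        counts[node_index[a], marker_index[marker]] += count
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for members in b_neighbors.values():
        ordered = sorted(members)
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                graph.add_edge(u, v)
    node_counts = pd.DataFrame(counts, index=pd.Index(nodes, name="node"), columns=list(markers))
    return AnodeGraph(cell_id=g.cell_id, graph=graph, node_counts=node_counts)


def largest_component(ag: AnodeGraph) -> AnodeGraph:
    """Restrict to the largest connected component (ties broken by node order).

    Personalized PageRank is only well-defined within one component, so
    scoring always runs on the largest one; dropped-node counts are
    logged.
    """
    if ag.n_nodes == 0 or nx.is_connected(ag.graph):
        return ag
    components = sorted(
        nx.connected_components(ag.graph), key=lambda c: (-len(c), min(c))
    )
    keep = sorted(components[0])
    dropped = ag.n_nodes - len(keep)
    logger.info(
        "cell %s: dropping %d of %d A-nodes outside the largest component",
        ag.cell_id,
        dropped,
        ag.n_nodes,
    )
    sub = ag.graph.subgraph(keep).copy()
    return AnodeGraph(
        cell_id=ag.cell_id, graph=sub, node_counts=ag.node_counts.loc[keep]
    )
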