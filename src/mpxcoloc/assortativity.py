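"""Adjusted local assortativity for marker counts on A-node cell graphs.

Local assortativity assigns each vertex a score measuring whether, in its
random-walk neighborhood, connected vertices carry similar attribute
values (here: molecule counts of one antibody marker). The neighborhood
is weighted by personalized PageRank: a random walk that at each step
teleports back to the focal vertex with probability ``restart_probability``
and otherwise moves to a uniformly random neighbor.

Raw scores are unbounded and not comparable across cells, so they are
adjusted by a three-step transform ``rho = h . g . f``:

``f`` divides positive scores by the sum of positives and negative
scores by the sum of absolute negatives (signed normalization; both sign
blocks then sum to +1 / -1 and the field sums to zero when both signs
occur); ``g`` divides by the Euclidean norm (unit energy); ``h`` applies
the signed logarithm ``sgn(z) * ln(|z| + 1)``. The composition is bounded
in ``[-ln 2, +ln 2]`` componentwise, with 0 preserved as uniform mixing.

Two per-cell filters zero out low-information markers before adjustment:
a marker whose total count falls below the cell's isotype threshold (the
maximum total count among isotype-control markers), and a marker present
on no more than ``vertex_threshold`` vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .graph_model import AnodeGraph, PanelManifest

Stage = Literal["raw", "normalized", "standardized", "adjusted"]

#: componentwise bound of the adjusted score: h applied to a unit vector entry
SCORE_BOUND = float(np.log(2.0))


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the residual tolerance."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"personalized PageRank did not converge after {iterations} "
            f"iterations (L1 residual {residual:.3e})"
        )


@dataclass(frozen=True)
class AssortativityConfig:
    """Tunables of the local-assortativity computation.

    restart_probability
        Teleport probability back to the focal vertex (the complement of
        the PageRank damping factor); 0.15 corresponds to the common
        0.85 damping convention.
    weight_floor
        PageRank weights below this value are truncated to zero and the
        vector renormalized, localizing the score to the focal
        neighborhood.
    vertex_threshold
        A marker must be present on strictly more than this many
        vertices to be scored.
    """

    restart_probability: float = 0.15
    weight_floor: float = 1e-4
    vertex_threshold: int = 10
    isotype_filter_enabled: bool = True
    tol: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.restart_probability < 1.0:
            raise ValueError("restart_probability must lie in [0, 1)")
        if not 0.0 <= self.weight_floor < 1.0:
            raise ValueError("weight_floor must lie in [0, 1)")


@dataclass
class ScoreField:
    """Per-node scores of one marker in one cell, aligned with node order."""

    cell_id: str
    marker: str
    nodes: tuple[str, ...]
    values: np.ndarray
    stage: Stage

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.nodes),):
            raise ValueError("values must align one-to-one with nodes")

    def is_zero(self) -> bool:
        return bool(np.all(self.values == 0.0))

    def with_values(self, values: np.ndarray, stage: Stage) -> "ScoreField":
        return ScoreField(
            cell_id=self.cell_id,
            marker=self.marker,
            nodes=self.nodes,
            values=np.asarray(values, dtype=float),
            stage=stage,
        )


def _transition_matrix(g: AnodeGraph) -> np.ndarray:
    """Row-stochastic transition matrix of the simple random walk."""
    a = nx.to_numpy_array(g.graph, nodelist=list(g.nodes))
    deg = a.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("graph has isolated nodes; restrict to a connected component first")
    return a / deg[:, None]


def _floor_renormalize(w: np.ndarray, floor: float) -> np.ndarray:
    w = np.where(w < floor, 0.0, w)
    total = w.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("weight_floor zeroed out an entire PageRank vector")
    return w / total


def personalized_pagerank(
    g: AnodeGraph, focal_node: str, cfg: AssortativityConfig
) -> np.ndarray:
    """Random-walk-with-restart weights around one focal vertex.

    Power iteration of ``w <- alpha * e_focal + (1 - alpha) * w P`` with
    ``alpha = restart_probability``; after convergence, weights below
    ``weight_floor`` are zeroed and the vector renormalized to sum 1.
    """
    nodes = g.nodes
    if focal_node not in set(nodes):
        raise KeyError(f"focal node {focal_node!r} not in graph")
    alpha = cfg.restart_probability
    n = g.n_nodes
    e = np.zeros(n)
    e[nodes.index(focal_node)] = 1.0
    if alpha == 1.0:  # pure teleport limit
        return e
    p = _transition_matrix(g)
    w = e.copy()
    for _ in range(cfg.max_iter):
        w_next = alpha * e + (1.0 - alpha) * (w @ p)
        residual = float(np.abs(w_next - w).sum())
        w = w_next
        if residual < cfg.tol:
            return _floor_renormalize(w, cfg.weight_floor)
    raise ConvergenceError(cfg.max_iter, residual)


def pagerank_weight_matrix(g: AnodeGraph, cfg: AssortativityConfig) -> np.ndarray:
    """Personalized PageRank weights for every focal vertex at once.

    Row ``i`` holds the weight vector for focal node ``g.nodes[i]``; a
    single batched power iteration replaces one iteration per vertex,
    with the same fixed point and the same floor-and-renormalize step.
    """
    alpha = cfg.restart_probability
    n = g.n_nodes
    eye = np.eye(n)
    if alpha == 1.0:
        return eye
    p = _transition_matrix(g)
    w = eye.copy()
    for _ in range(cfg.max_iter):
        w_next = alpha * eye + (1.0 - alpha) * (w @ p)
        residual = float(np.abs(w_next - w).sum(axis=1).max())
        w = w_next
        if residual < cfg.tol:
            return _floor_renormalize(w, cfg.weight_floor)
    raise ConvergenceError(cfg.max_iter, residual)


def raw_local_assortativity(
    g: AnodeGraph,
    marker: str,
    cfg: AssortativityConfig,
    weights: np.ndarray | None = None,
) -> ScoreField:
    """Per-vertex local assortativity of one marker's count vector.

    With attribute ``x``, edge-end mean ``mu_e = sum(d_v x_v) / sum(d_v)``
    and variance ``sigma_e^2`` defined analogously, the focal score is

        score(l) = (1 / sigma_e^2) * ( sum_v w_v(l) x_v nbrmean_v - mu_e^2 )

    where ``nbrmean_v`` is the mean attribute over v's neighbors and
    ``w(l)`` the personalized PageRank weights of ``l``. A constant
    attribute (``sigma_e = 0``) yields the all-zero field.
    """
    x = g.marker_vector(marker)
    d = g.degrees()
    dsum = d.sum()
    mu_e = float((d * x).sum() / dsum)
    var_e = float((d * x**2).sum() / dsum) - mu_e**2
    if var_e <= 0.0:
        return ScoreField(g.cell_id, marker, g.nodes, np.zeros(g.n_nodes), "raw")
    a = nx.to_numpy_array(g.graph, nodelist=list(g.nodes))
    nbr_mean = (a @ x) / d
    if weights is None:
        weights = pagerank_weight_matrix(g, cfg)
    scores = (weights @ (x * nbr_mean) - mu_e**2) / var_e
    return ScoreField(g.cell_id, marker, g.nodes, scores, "raw")


def normalize_signed(s: ScoreField) -> ScoreField:
    """Signed normalization f: each sign block rescaled to total 1 in magnitude."""
    if s.stage != "raw":
        raise ValueError(f"normalize_signed expects a raw field, got {s.stage}")
    x = s.values
    out = np.zeros_like(x)
    pos_sum = x[x > 0].sum()
    neg_sum = np.abs(x[x < 0]).sum()
    if pos_sum > 0:
        out[x > 0] = x[x > 0] / pos_sum
    if neg_sum > 0:
        out[x < 0] = x[x < 0] / neg_sum
    return s.with_values(out, "normalized")


def standardize(s: ScoreField) -> ScoreField:
    """Unit-energy standardization g: divide by the Euclidean norm."""
    if s.stage != "normalized":
        raise ValueError(f"standardize expects a normalized field, got {s.stage}")
    norm = float(np.sqrt((s.values**2).sum()))
    if norm == 0.0:
        return s.with_values(s.values.copy(), "standardized")
    return s.with_values(s.values / norm, "standardized")


def signed_log(s: ScoreField) -> ScoreField:
    """Signed log h: ``z -> sgn(z) * ln(|z| + 1)``; yields the adjusted score."""
    if s.stage != "standardized":
        raise ValueError(f"signed_log expects a standardized field, got {s.stage}")
    z = s.values
    return s.with_values(np.sign(z) * np.log1p(np.abs(z)), "adjusted")


def isotype_threshold(g: AnodeGraph, panel: PanelManifest) -> int:
    """Per-cell noise floor: max total count among isotype-control markers."""
    if not panel.isotype_markers:
        raise ValueError("panel has no isotype markers; cannot compute isotype threshold")
    totals = [int(g.node_counts[m].sum()) for m in sorted(panel.isotype_markers)]
    return max(totals)


def adjusted_local_assortativity(
    g: AnodeGraph,
    marker: str,
    cfg: AssortativityConfig,
    panel: PanelManifest,
    weights: np.ndarray | None = None,
) -> ScoreField:
    """Filtered, bounded adjusted local assortativity ``rho`` of one marker.

    The all-zero field is returned when the marker's total count is
    below the cell's isotype threshold or the marker sits on no more
    than ``vertex_threshold`` vertices; otherwise
    ``rho = signed_log(standardize(normalize_signed(raw)))``.
    """
    x = g.marker_vector(marker)
    zero = ScoreField(g.cell_id, marker, g.nodes, np.zeros(g.n_nodes), "adjusted")
    if cfg.isotype_filter_enabled and x.sum() < isotype_threshold(g, panel):
        return zero
    if int((x > 0).sum()) <= cfg.vertex_threshold:
        return zero
    raw = raw_local_assortativity(g, marker, cfg, weights=weights)
    return signed_log(standardize(normalize_signed(raw)))


def filter_reasons(
    g: AnodeGraph, marker: str, cfg: AssortativityConfig, panel: PanelManifest
) -> list[str]:
    """Human-readable reasons a marker would be zeroed in this cell, if any."""
    reasons = []
    x = g.marker_vector(marker)
    if cfg.isotype_filter_enabled:
        thr = isotype_threshold(g, panel)
        if x.sum() < thr:
            reasons.append(f"total count {int(x.sum())} below isotype threshold {thr}")
    n_vertices = int((x > 0).sum())
    if n_vertices <= cfg.vertex_threshold:
        reasons.append(
            f"present on {n_vertices} vertices (threshold requires > {cfg.vertex_threshold})"
        )
    return reasons


def score_cell(
    g: AnodeGraph,
    panel: PanelManifest,
    cfg: AssortativityConfig,
    markers: Iterable[str] | None = None,
) -> dict[str, ScoreField]:
    """Adjusted score fields for several markers, sharing one PPR matrix.

    The PageRank weights depend only on the graph, so they are computed
    once per cell and reused across the whole panel.
    """
    if markers is None:
        markers = panel.markers
    weights = pagerank_weight_matrix(g, cfg)
    return {
        m: adjusted_local_assortativity(g, m, cfg, panel, weights=weights)
        for m in markers
    }


def scores_to_table(fields: Iterable[ScoreField]) -> pd.DataFrame:
    """Long-format table (cell_id, marker, node_id, adjusted_score)."""
    rows = []
    for f in fields:
        for node, value in zip(f.nodes, f.values):
            rows.append((f.cell_id, f.marker, node, value))
    return pd.DataFrame(rows, columns=["cell_id", "marker", "node_id", "adjusted_score"])


def table_to_scores(df: pd.DataFrame, stage: Stage = "adjusted") -> dict[tuple[str, str], ScoreField]:
    """Inverse of :func:`scores_to_table`, keyed by (cell_id, marker)."""
    out: dict[tuple[str, str], ScoreField] = {}
    for (cell_id, marker), sub in df.groupby(["cell_id", "marker"], sort=True):
        out[(str(cell_id), str(marker))] = ScoreField(
            cell_id=str(cell_id),
            marker=str(marker),
            nodes=tuple(sub["node_id"].astype(str)),
            values=sub["adjusted_score"].to_numpy(dtype=float),
            stage=stage,
        )
    return out
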