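"""Pairwise, higher-order and differential protein colocalization.

Pairwise colocalization of two markers in one cell is the Spearman rank
correlation of their adjusted local-assortativity fields over the cell's
vertices (average ranks on ties); if either field is all-zero — a
filtered or uniformly mixing marker — the score is defined as exactly 0.

Higher-order colocalization of k >= 3 markers compares the vertex sets
where each marker is assortative (adjusted score > 0) with the
multiple-site similarity measure from community ecology,

    C_T = (T / (T - 1)) * (1 - |union A_i| / sum |A_i|),

which reduces to the Sorensen index 2|A n B| / (|A| + |B|) at T = 2.

Differential colocalization between two samples reports the difference
of per-cell score means together with a two-sided Wilcoxon rank-sum
p-value, binned into 0-3 significance dots at 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assortativity import ScoreField

#: largest number of rank assignments enumerated by the exact Wilcoxon test
MAX_EXACT_COMBINATIONS = 200_000


@dataclass(frozen=True)
class ColocalizationRecord:
    """One cell x one marker combination -> one colocalization score."""

    cell_id: str
    markers: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(sorted(self.markers)))
        if len(self.markers) < 2:
            raise ValueError("a colocalization record needs at least two markers")

    @property
    def order(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class DifferentialResult:
    """Mean difference of per-cell scores between two samples plus Wilcoxon p."""

    markers: tuple[str, ...]
    mean_a: float
    mean_b: float
    p_value: float

    @property
    def mean_diff(self) -> float:
        return self.mean_a - self.mean_b

    @property
    def order(self) -> int:
        return len(self.markers)

    @property
    def dots(self) -> int:
        return dots_from_p(self.p_value)


def dots_from_p(p: float) -> int:
    """Significance category: 0 (p > 0.01) up to 3 (p <= 0.0001)."""
    if p <= 0.0001:
        return 3
    if p <= 0.001:
        return 2
    if p <= 0.01:
        return 1
    return 0


def _check_aligned(x: ScoreField, y: ScoreField) -> None:
    if x.cell_id != y.cell_id:
        raise ValueError(f"fields from different cells: {x.cell_id!r} vs {y.cell_id!r}")
    if x.nodes != y.nodes:
        raise ValueError("fields have misaligned node sets")


def pairwise_colocalization(x: ScoreField, y: ScoreField) -> float:
    """Spearman correlation of two adjusted fields; 0 if either is all-zero."""
    _check_aligned(x, y)
    if x.is_zero() or y.is_zero():
        return 0.0
    with warnings.catch_warnings():
        # constant non-zero fields make the correlation undefined; by the
        # uniform-mixing convention those carry no colocalization signal
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x.values, y.values).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def colocalization_matrix(
    cell_scores: Mapping[str, ScoreField], markers: Sequence[str] | None = None
) -> list[ColocalizationRecord]:
    """All unordered marker-pair records for one cell."""
    if markers is None:
        markers = sorted(cell_scores)
    records = []
    for m1, m2 in itertools.combinations(sorted(markers), 2):
        score = pairwise_colocalization(cell_scores[m1], cell_scores[m2])
        records.append(
            ColocalizationRecord(
                cell_id=cell_scores[m1].cell_id, markers=(m1, m2), score=score
            )
        )
    return records


def positive_node_set(x: ScoreField) -> set[str]:
    """Vertices where the marker is assortative: adjusted score strictly > 0."""
    return {node for node, v in zip(x.nodes, x.values) if v > 0.0}


def multisite_similarity(sets: Sequence[set]) -> float:
    """Multiple-site similarity of T >= 2 sets; 0 when all sets are empty."""
    t = len(sets)
    if t < 2:
        raise ValueError(f"multisite similarity needs at least 2 sets, got {t}")
    size_sum = sum(len(s) for s in sets)
    if size_sum == 0:
        return 0.0
    union = set().union(*sets)
    return (t / (t - 1)) * (1.0 - len(union) / size_sum)


def higher_order_colocalization(
    cell_scores: Mapping[str, ScoreField], markers: Sequence[str]
) -> ColocalizationRecord:
    """Multi-marker colocalization from the positive-score vertex sets.

    Filtered (all-zero) markers contribute empty sets, lowering the
    score of any tuple that includes them.
    """
    sets = [positive_node_set(cell_scores[m]) for m in markers]
    cell_id = cell_scores[markers[0]].cell_id
    return ColocalizationRecord(
        cell_id=cell_id, markers=tuple(markers), score=multisite_similarity(sets)
    )


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration over all assignments of pooled ranks to the first
    group when their number is at most ``MAX_EXACT_COMBINATIONS``
    (ties handled exactly via average ranks); otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    if comb(n1 + n2, n1) <= MAX_EXACT_COMBINATIONS:
        return _exact_rank_sum_p(a, b)
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(p)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Enumerate every assignment of pooled ranks to group a."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = a.size
    observed = ranks[:n1].sum()
    eps = 1e-9
    le = ge = total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= observed + eps:
            le += 1
        if w >= observed - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def differential(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    markers: Sequence[str],
) -> DifferentialResult:
    """Differential colocalization of one marker tuple between two samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need at least 2 cells per sample for {tuple(markers)}; "
            f"got {a.size} and {b.size}"
        )
    return DifferentialResult(
        markers=tuple(sorted(markers)),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        p_value=wilcoxon_rank_sum(a, b),
    )


def records_to_table(records: Iterable[ColocalizationRecord]) -> pd.DataFrame:
    """Long colocalization table (cell_id, markers, order, score)."""
    rows = [
        (r.cell_id, "+".join(r.markers), r.order, r.score) for r in records
    ]
    return pd.DataFrame(rows, columns=["cell_id", "markers", "order", "score"])


def differential_table(
    results: Iterable[DifferentialResult], benjamini_hochberg: bool = False
) -> pd.DataFrame:
    """Differential table; optional Benjamini-Hochberg adjusted column."""
    results = list(results)
    df = pd.DataFrame(
        [
            (
                "+".join(r.markers),
                r.order,
                r.mean_a,
                r.mean_b,
                r.mean_diff,
                r.p_value,
                r.dots,
            )
            for r in results
        ],
        columns=["markers", "order", "mean_a", "mean_b", "mean_diff", "p_value", "dots"],
    )
    if benjamini_hochberg and len(df):
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        q = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            q[i] = running
        df["q_value"] = q
    return df


def permutation_null(
    g,
    marker: str,
    cfg,
    panel,
    n_perm: int,
    seed: int,
) -> ScoreField:
    """Permutation-corrected adjusted field for one marker.

    The marker's per-node count vector is permuted uniformly at random
    across vertices ``n_perm`` times, the adjusted field recomputed per
    permutation, and the per-node permutation mean subtracted from the
    observed field. The filters are permutation-invariant (totals and
    vertex occupancy do not change), so a filtered marker stays all-zero.
    ``n_perm = 0`` disables the correction and returns the observed field.
    """
    from .assortativity import adjusted_local_assortativity, pagerank_weight_matrix
    from .graph_model import AnodeGraph

    if n_perm < 0:
        raise ValueError("n_perm must be non-negative")
    weights = pagerank_weight_matrix(g, cfg)
    observed = adjusted_local_assortativity(g, marker, cfg, panel, weights=weights)
    if n_perm == 0 or observed.is_zero():
        return observed
    rng = np.random.default_rng(seed)
    counts = g.node_counts[marker].to_numpy()
    acc = np.zeros_like(observed.values)
    for _ in range(n_perm):
        shuffled = g.node_counts.copy()
        shuffled[marker] = rng.permutation(counts)
        g_perm = AnodeGraph(cell_id=g.cell_id, graph=g.graph, node_counts=shuffled)
        acc += adjusted_local_assortativity(
            g_perm, marker, cfg, panel, weights=weights
        ).values
    return observed.with_values(observed.values - acc / n_perm, "adjusted")
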