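"""Synthetic MPX-like cells with controllable surface polarity.

A cell surface is modeled as A-pixels placed uniformly on the unit
sphere. Each B-pixel picks a random anchor point and attaches to the
``mean_b_degree`` nearest A-pixels, so the A-node projection is locally
clustered and mimics the neighborhood structure of real pixel graphs.

Marker molecules are drawn Poisson per A-pixel and scattered uniformly
over that pixel's incident edges. Polarized markers share one contiguous
polar cap (the ``cap_fraction`` of A-pixels nearest a random pole) where
their Poisson rate is multiplied by ``enrichment_fold``; the rate outside
the cap is scaled down so the expected total per marker is independent
of the fold — polarization redistributes abundance, it does not inflate
it. Isotype controls always stay uniform at a low rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph_model import BipartiteCellGraph, PanelManifest, project_to_anodes

DEFAULT_MARKERS = ("CD50", "CD162", "CD44", "CD37", "CD20", "CD54", "CD18", "CD45")
DEFAULT_ISOTYPES = ("mIgG2b", "mIgG1", "mIgG2a")


def default_panel() -> PanelManifest:
    """Small uropod-flavored panel: 8 specific markers + 3 mouse isotypes."""
    return PanelManifest(
        markers=DEFAULT_MARKERS + DEFAULT_ISOTYPES,
        isotype_markers=frozenset(DEFAULT_ISOTYPES),
    )


@dataclass(frozen=True)
class SyntheticCellConfig:
    """Parameters of one simulated cell.

    baseline_rate is the expected molecule count per A-pixel for each
    specific marker (a scalar or a per-marker mapping); isotype_rate the
    same for isotype controls. Polarized markers share one cap covering
    ``cap_fraction`` of A-pixels with rate multiplied by
    ``enrichment_fold`` inside and rescaled outside to conserve the
    expected total.
    """

    n_a_pixels: int = 300
    n_b_pixels: int = 600
    mean_b_degree: int = 4
    panel: PanelManifest = field(default_factory=default_panel)
    baseline_rate: float | Mapping[str, float] = 2.0
    polarized_markers: tuple[str, ...] = ()
    cap_fraction: float = 0.2
    enrichment_fold: float = 1.0
    isotype_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cap_fraction < 1.0:
            raise ValueError("cap_fraction must lie strictly between 0 and 1")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        unknown = set(self.polarized_markers) - set(self.panel.markers)
        if unknown:
            raise ValueError(f"polarized markers not in panel: {sorted(unknown)}")
        iso = set(self.polarized_markers) & self.panel.isotype_markers
        if iso:
            raise ValueError(f"isotype controls cannot be polarized: {sorted(iso)}")

    def rate_of(self, marker: str) -> float:
        if marker in self.panel.isotype_markers:
            return float(self.isotype_rate)
        if isinstance(self.baseline_rate, Mapping):
            return float(self.baseline_rate[marker])
        return float(self.baseline_rate)


def _unit_sphere_points(rng: np.random.Generator, n: int) -> np.ndarray:
    pts = rng.standard_normal((n, 3))
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def simulate_cell(cfg: SyntheticCellConfig, cell_id: str | None = None) -> BipartiteCellGraph:
    """Simulate one cell; fully determined by ``cfg`` (including its seed).

    Geometries whose A-node projection comes out disconnected are
    redrawn up to 10 times before raising.
    """
    rng = np.random.default_rng(cfg.seed)
    if cell_id is None:
        cell_id = f"cell_{cfg.seed:010d}"
    last_err = None
    for _attempt in range(10):
        a_pos = _unit_sphere_points(rng, cfg.n_a_pixels)
        anchors = _unit_sphere_points(rng, cfg.n_b_pixels)
        # each B-pixel links the mean_b_degree A-pixels nearest its anchor
        dots = anchors @ a_pos.T
        nearest = np.argpartition(-dots, cfg.mean_b_degree - 1, axis=1)[
            :, : cfg.mean_b_degree
        ]
        incident: list[list[int]] = [[] for _ in range(cfg.n_a_pixels)]
        for b_idx, a_indices in enumerate(nearest):
            for a_idx in a_indices:
                incident[a_idx].append(b_idx)
        if min(len(bs) for bs in incident) == 0:
            last_err = "isolated A-pixel"
            continue
        graph = _draw_counts(cfg, rng, cell_id, a_pos, incident)
        projection = project_to_anodes(graph, cfg.panel)
        if projection.is_connected():
            return graph
        last_err = "disconnected A-node projection"
    raise RuntimeError(
        f"could not generate a connected cell after 10 attempts ({last_err}); "
        "increase n_b_pixels or mean_b_degree"
    )


def _draw_counts(
    cfg: SyntheticCellConfig,
    rng: np.random.Generator,
    cell_id: str,
    a_pos: np.ndarray,
    incident: list[list[int]],
) -> BipartiteCellGraph:
    n = cfg.n_a_pixels
    n_cap = max(1, int(round(cfg.cap_fraction * n)))
    pole = _unit_sphere_points(rng, 1)[0]
    cap = set(np.argsort(-(a_pos @ pole))[:n_cap])  # contiguous polar cap

    a_ids = [f"{cell_id}:a{i:05d}" for i in range(n)]
    b_ids = [f"{cell_id}:b{i:05d}" for i in range(cfg.n_b_pixels)]
    edges: dict[tuple[str, str, str], int] = {}
    for marker in cfg.panel.markers:
        base = cfg.rate_of(marker)
        if marker in cfg.polarized_markers and cfg.enrichment_fold > 1.0:
            # conserve the expected total: n*base = n_cap*fold*r_out + (n-n_cap)*r_out
            r_out = base * n / (n_cap * cfg.enrichment_fold + (n - n_cap))
            rates = np.full(n, r_out)
            rates[list(cap)] = cfg.enrichment_fold * r_out
        else:
            rates = np.full(n, base)
        counts = rng.poisson(rates)
        for a_idx in np.flatnonzero(counts):
            slots = incident[a_idx]
            split = rng.multinomial(counts[a_idx], np.full(len(slots), 1.0 / len(slots)))
            for b_idx, c in zip(slots, split):
                if c > 0:
                    key = (a_ids[a_idx], b_ids[b_idx], marker)
                    edges[key] = edges.get(key, 0) + int(c)
    b_used = {b for (_, b, _) in edges}
    return BipartiteCellGraph(
        cell_id=cell_id,
        a_nodes=set(a_ids),
        b_nodes=b_used if b_used else set(b_ids[:1]),
        edges=edges,
    )


def derive_cell_seeds(seed: int, n_cells: int) -> list[int]:
    """Independent per-cell seeds spawned deterministically from one seed."""
    children = np.random.SeedSequence(seed).spawn(n_cells)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def simulate_population(
    cfg: SyntheticCellConfig, n_cells: int, condition_label: str = "sample"
) -> list[BipartiteCellGraph]:
    """Independent cells with per-cell seeds derived from ``cfg.seed``."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    cells = []
    for i, cell_seed in enumerate(derive_cell_seeds(cfg.seed, n_cells)):
        cell_cfg = replace(cfg, seed=cell_seed)
        cells.append(simulate_cell(cell_cfg, cell_id=f"{condition_label}_{i:03d}"))
    return cells


def sample_sheet(
    populations: Mapping[str, Sequence[BipartiteCellGraph]],
    seeds: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Sample sheet (cell_id, condition[, seed]) for labeled populations."""
    rows = []
    for condition, cells in populations.items():
        cond_seeds = seeds.get(condition) if seeds is not None else [None] * len(cells)
        for cell, s in zip(cells, cond_seeds):
            rows.append((cell.cell_id, condition, s))
    df = pd.DataFrame(rows, columns=["cell_id", "condition", "seed"])
    return df.drop(columns="seed") if seeds is None else df
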