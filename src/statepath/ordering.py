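"""Pseudo-temporal ordering of cells along a landmark path.

Given an ordered sequence of landmarks (a, b, c, ...) whose consecutive
pairs are edges of the state-transition tree, each transitional cell is
orthogonally projected onto the line spanned by its edge's two centroids
and cells are sorted edge by edge by their projection scalar.  Cells
falling before the first landmark or after the last one are kept on the
extensions of the terminal edges; on interior edges the projection is
clamped to the segment.  The pseudotime coordinate is the Euclidean arc
length through the centroids up to the projection point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .landmarks import LandmarkSet
from .network import EdgeAssignment, StateTransitionNetwork, assign_edges


class PathError(ValueError):
    """A landmark path inconsistent with the state-transition tree."""


@dataclass
class EdgePlacement:
    """Orthogonal projection of one cell onto one landmark edge."""

    cell_id: str
    edge: tuple[str, str]
    t: float  # 0 at the first landmark, 1 at the second
    residual: float  # perpendicular distance to the line


@dataclass
class PathOrdering:
    """Ordered cells along a landmark path.

    ``table`` columns: path_name, segment_index (0-based along the path),
    t (projection scalar on that segment), pseudotime (cumulative arc
    length), rank (0-based position in the ordering); indexed by cell id in
    pseudo-temporal order.  ``segment_lengths`` are the centroid-to-centroid
    Euclidean distances.
    """

    path: list[str]
    table: pd.DataFrame
    segment_lengths: list[float]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def total_length(self) -> float:
        return float(sum(self.segment_lengths))

    @property
    def pseudotime(self) -> pd.Series:
        return self.table["pseudotime"]


def validate_path(path: list[str], stn: StateTransitionNetwork) -> None:
    if len(path) < 2:
        raise PathError("a path needs at least 2 landmarks")
    if len(set(path)) != len(path):
        raise PathError("path revisits a landmark")
    for a, b in zip(path, path[1:]):
        if not stn.has_edge(a, b):
            raise PathError(f"({a}, {b}) is not an edge of the state-transition tree")


def project_onto_edge(
    cell_vector: np.ndarray, a: np.ndarray, b: np.ndarray, cell_id: str = "",
    edge: tuple[str, str] = ("a", "b"),
) -> EdgePlacement:
    """Project a cell onto the line through centroids ``a`` and ``b``.

    t = ((x-a)·(b-a)) / ||b-a||²; the residual is the perpendicular
    distance from the cell to the line.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.asarray(cell_vector, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise ValueError(f"degenerate edge {edge}: coincident landmarks")
    t = float((x - a) @ ab) / denom
    residual = float(np.linalg.norm(x - (a + t * ab)))
    return EdgePlacement(cell_id=cell_id, edge=edge, t=t, residual=residual)


def assign_cells_to_path(
    ea: EdgeAssignment,
    path: list[str],
    rescue: bool = False,
    ls: LandmarkSet | None = None,
    m: ExpressionMatrix | None = None,
) -> tuple[dict[tuple[str, str], list[str]], list[str]]:
    """Group cells onto the path's edges by their nearest-landmark pair.

    A cell belongs to edge (a, b) iff its two nearest landmarks are exactly
    {a, b}.  With ``rescue`` on, a cell whose pair is not a path edge but
    whose single nearest landmark lies on the path is attached to the
    incident path edge with the smallest perpendicular residual (requires
    ``ls`` and ``m``).  Returns (edge -> cell ids, excluded cell ids).
    """
    path_edges = [tuple(sorted(e)) for e in zip(path, path[1:])]
    edge_order = {tuple(sorted(e)): e for e in zip(path, path[1:])}
    assigned: dict[tuple[str, str], list[str]] = {e: [] for e in zip(path, path[1:])}
    excluded: list[str] = []
    on_path = set(path)
    for cell_id, row in ea.table.iterrows():
        key = tuple(sorted((row["first"], row["second"])))
        if key in edge_order:
            assigned[edge_order[key]].append(cell_id)
            continue
        if rescue and row["first"] in on_path:
            if ls is None or m is None:
                raise ValueError("rescue mode needs the landmark set and matrix")
            nearest = row["first"]
            i = path.index(nearest)
            incident = []
            if i > 0:
                incident.append((path[i - 1], path[i]))
            if i < len(path) - 1:
                incident.append((path[i], path[i + 1]))
            x = m.data[cell_id].values
            best = min(
                incident,
                key=lambda e: project_onto_edge(
                    x, ls.centroids[e[0]].values, ls.centroids[e[1]].values
                ).residual,
            )
            assigned[best].append(cell_id)
            continue
        excluded.append(cell_id)
    return assigned, excluded


def order_cells_along_path(
    m: ExpressionMatrix,
    ls: LandmarkSet,
    stn: StateTransitionNetwork,
    path: list[str],
    rescue: bool = False,
    path_name: str | None = None,
) -> PathOrdering:
    """Order cells along ``path`` by orthogonal projection.

    Within each edge cells are sorted by ascending projection scalar t
    (ties broken by cell id), and the per-edge orderings are concatenated.
    On interior edges t is clamped to [0, 1]; on the first edge t < 0 and on
    the last edge t > 1 are kept as extensions beyond the terminal
    landmarks.  Pseudotime is the arc length: the summed lengths of
    completed segments plus t times the current segment length.
    """
    validate_path(path, stn)
    path_name = path_name or "-".join(path)
    ea = assign_edges(m, ls)
    assigned, _excluded = assign_cells_to_path(ea, path, rescue=rescue, ls=ls, m=m)

    seg_lengths = [
        float(np.linalg.norm(ls.centroids[b].values - ls.centroids[a].values))
        for a, b in zip(path, path[1:])
    ]
    n_seg = len(seg_lengths)
    offsets = np.concatenate([[0.0], np.cumsum(seg_lengths)])

    rows = []
    for seg_idx, (a, b) in enumerate(zip(path, path[1:])):
        ca, cb = ls.centroids[a].values, ls.centroids[b].values
        placements = [
            project_onto_edge(m.data[c].values, ca, cb, cell_id=c, edge=(a, b))
            for c in assigned[(a, b)]
        ]
        placements.sort(key=lambda p: (p.t, p.cell_id))
        for p in placements:
            t_eff = p.t
            if seg_idx > 0:
                t_eff = max(t_eff, 0.0)
            if seg_idx < n_seg - 1:
                t_eff = min(t_eff, 1.0)
            rows.append(
                {
                    "cell_id": p.cell_id,
                    "path_name": path_name,
                    "segment_index": seg_idx,
                    "t": t_eff,
                    "pseudotime": offsets[seg_idx] + t_eff * seg_lengths[seg_idx],
                    "residual": p.residual,
                }
            )
    table = pd.DataFrame(
        rows, columns=["cell_id", "path_name", "segment_index", "t", "pseudotime", "residual"]
    ).set_index("cell_id")
    table["rank"] = np.arange(len(table))
    return PathOrdering(path=list(path), table=table, segment_lengths=seg_lengths)


def write_ordering(po: PathOrdering, path) -> None:
    po.table.rename_axis("cell_id").to_csv(path, sep="\t")
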