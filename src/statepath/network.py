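"""Neighborhood network of landmarks and its spanning-tree trimming.

Every cell sits somewhere on the continuum between cell states.  Its two
nearest landmarks (Euclidean distance to the centroids) nominate a putative
state transition, and the number of cells nominating a given landmark pair
is the weight of that edge.  Trimming keeps the spanning tree of maximum
total weight — the transitions supported by the most cells — which is the
inferred state-transition network.  Unlike a centroid-distance MST, edge
support here is transitional-cell count, which separates transcriptionally
similar end states that no cells actually bridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .landmarks import LandmarkSet


@dataclass
class EdgeAssignment:
    """Per-cell nearest landmark pair and the two distances.

    ``table`` columns: first, second (landmark names, distance-sorted),
    dist1 <= dist2.  Indexed by cell id.
    """

    table: pd.DataFrame

    def pair(self, cell_id: str) -> frozenset[str]:
        row = self.table.loc[cell_id]
        return frozenset((row["first"], row["second"]))


@dataclass
class NeighborhoodNetwork:
    """Landmark graph weighted by transitional-cell counts.

    ``weights`` maps each unordered landmark pair (as a sorted tuple) to its
    cell count; ``members`` to the supporting cell ids.  Pairs with zero
    support are absent.
    """

    nodes: list[str]
    weights: dict[tuple[str, str], int]
    members: dict[tuple[str, str], list[str]]

    @property
    def total_weight(self) -> int:
        return sum(self.weights.values())

    def weight(self, a: str, b: str) -> int:
        return self.weights.get(tuple(sorted((a, b))), 0)


@dataclass
class StateTransitionNetwork:
    """Spanning tree of landmarks retained after trimming."""

    nodes: list[str]
    edges: list[tuple[str, str]]  # sorted tuples
    weights: dict[tuple[str, str], int]
    members: dict[tuple[str, str], list[str]]

    def has_edge(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in set(self.edges)

    @property
    def total_weight(self) -> int:
        return sum(self.weights[e] for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b in self.edges:
            g.add_edge(a, b, weight=self.weights.get((a, b), 0))
        return g


def nearest_two_landmarks(
    cell_vector: np.ndarray, ls: LandmarkSet
) -> tuple[tuple[str, str], tuple[float, float]]:
    """The two landmarks nearest to a cell, ties broken by name order."""
    names = ls.names
    if len(names) < 2:
        raise ValueError("need at least 2 landmarks")
    diffs = ls.centroids.values - np.asarray(cell_vector, dtype=float)[:, None]
    dists = np.sqrt((diffs**2).sum(axis=0))
    name_rank = np.argsort(np.argsort(names))
    order = np.lexsort((name_rank, dists))
    i, j = order[0], order[1]
    return (names[i], names[j]), (float(dists[i]), float(dists[j]))


def assign_edges(m: ExpressionMatrix, ls: LandmarkSet) -> EdgeAssignment:
    """Nearest landmark pair for every cell of the matrix (vectorized)."""
    names = ls.names
    if len(names) < 2:
        raise ValueError("need at least 2 landmarks")
    X = m.values  # genes x cells
    C = ls.centroids.loc[m.gene_ids].values  # genes x landmarks
    # squared distances via the expansion ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2
    d2 = (
        (X**2).sum(axis=0)[:, None]
        - 2.0 * X.T @ C
        + (C**2).sum(axis=0)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    dists = np.sqrt(d2)  # cells x landmarks
    # stable tie-break by landmark name order
    name_rank = np.argsort(np.argsort(names))
    order = np.lexsort((np.broadcast_to(name_rank, dists.shape), dists), axis=1)
    first_idx, second_idx = order[:, 0], order[:, 1]
    rows = np.arange(dists.shape[0])
    table = pd.DataFrame(
        {
            "first": np.array(names)[first_idx],
            "second": np.array(names)[second_idx],
            "dist1": dists[rows, first_idx],
            "dist2": dists[rows, second_idx],
        },
        index=pd.Index(m.cell_ids, name="cell_id"),
    )
    return EdgeAssignment(table)


def build_neighborhood_network(
    m: ExpressionMatrix, ls: LandmarkSet
) -> NeighborhoodNetwork:
    """Count cells per nearest-landmark pair; Σ weights = number of cells."""
    ea = assign_edges(m, ls)
    weights: dict[tuple[str, str], int] = {}
    members: dict[tuple[str, str], list[str]] = {}
    for cell_id, row in ea.table.iterrows():
        key = tuple(sorted((row["first"], row["second"])))
        weights[key] = weights.get(key, 0) + 1
        members.setdefault(key, []).append(cell_id)
    return NeighborhoodNetwork(nodes=ls.names, weights=weights, members=members)


def trim_network(nn: NeighborhoodNetwork) -> StateTransitionNetwork:
    """Maximum-weight spanning tree over the landmark graph.

    Equivalent to a minimum spanning tree under distance -w(e).  The trim is
    run over the complete landmark graph with unsupported pairs at weight 0,
    so a spanning tree always exists even when the observed neighborhood
    graph is disconnected; any retained zero-weight edge triggers a warning.
    Deterministic: greedy union-find insertion over edges sorted by weight
    descending, then lexicographic endpoint names.
    """
    nodes = sorted(nn.nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 landmarks to trim")
    candidates = [
        (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]
    ]
    candidates.sort(key=lambda e: (-nn.weight(*e), e[0], e[1]))

    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[str, str]] = []
    for a, b in candidates:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b))
            if len(edges) == len(nodes) - 1:
                break
    zero = [e for e in edges if nn.weight(*e) == 0]
    if zero:
        warnings.warn(
            f"{len(zero)} retained edges have zero cell support "
            f"(neighborhood network disconnected): {zero}",
            stacklevel=2,
        )
    edges.sort()
    return StateTransitionNetwork(
        nodes=list(nn.nodes),
        edges=edges,
        weights={e: nn.weight(*e) for e in edges},
        members={e: nn.members.get(e, []) for e in edges},
    )


def write_network(
    nn: NeighborhoodNetwork, stn: StateTransitionNetwork | None, path
) -> None:
    """Edge-list TSV: landmark_a, landmark_b, weight, retained_flag."""
    retained = set(stn.edges) if stn is not None else set()
    keys = sorted(set(nn.weights) | retained)
    rows = [
        {
            "landmark_a": a,
            "landmark_b": b,
            "weight": nn.weight(a, b),
            "retained": int((a, b) in retained),
        }
        for a, b in keys
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(stn: StateTransitionNetwork, path) -> None:
    nx.write_graphml(stn.to_networkx(), path)
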