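"""Evaluation utilities for synthetic benchmarks.

Recovered state-transition trees live on landmarks, several of which may
represent stretches of the same generative state; comparisons against a
known topology therefore collapse landmarks to their majority group label
first.  Also provides a plain centroid-distance MST as a contrast to the
transitional-cell-count trimming, and Spearman ordering accuracy against
recorded ground-truth positions.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .landmarks import LandmarkSet
from .network import StateTransitionNetwork
from .ordering import PathOrdering
from .simulate import SyntheticDataset


def landmark_majority(ls: LandmarkSet, ann: pd.Series) -> dict[str, str]:
    """Majority group label of each landmark's member cells."""
    out = {}
    for name in ls.names:
        counts = ann.loc[ls.members(name)].value_counts()
        top = counts.max()
        out[name] = sorted(counts.index[counts == top])[0]
    return out


def collapse_to_states(
    stn: StateTransitionNetwork, ls: LandmarkSet, ann: pd.Series
) -> set[frozenset[str]]:
    """Contract same-majority landmarks; return the state-level edge set."""
    majority = landmark_majority(ls, ann)
    edges = set()
    for a, b in stn.edges:
        sa, sb = majority[a], majority[b]
        if sa != sb:
            edges.add(frozenset((sa, sb)))
    return edges


def topology_recovered(
    stn: StateTransitionNetwork, ls: LandmarkSet, ann: pd.Series, ds: SyntheticDataset
) -> bool:
    """Does the landmark tree collapse exactly onto the generative topology?

    Requires every generative state to be represented by some landmark and
    the collapsed edge set to equal the generative (undirected) edge set.
    """
    majority = landmark_majority(ls, ann)
    if set(majority.values()) != set(ds.topology.states):
        return False
    return collapse_to_states(stn, ls, ann) == ds.topology.undirected_edge_set()


def branch_landmark_path(
    stn: StateTransitionNetwork,
    ls: LandmarkSet,
    ann: pd.Series,
    root_state: str,
    leaf_state: str,
) -> list[str]:
    """Landmark path across the tree from a root-state landmark to a
    leaf-state landmark, preferring tree leaves so the path spans the whole
    branch."""
    majority = landmark_majority(ls, ann)
    g = stn.to_networkx()

    def endpoint(state: str) -> str:
        cands = [n for n in g.nodes if majority[n] == state]
        if not cands:
            raise ValueError(f"no landmark has majority state {state!r}")
        leaves = [n for n in cands if g.degree[n] == 1]
        return sorted(leaves or cands)[0]

    return nx.shortest_path(g, endpoint(root_state), endpoint(leaf_state))


def ordering_accuracy(po: PathOrdering, ds: SyntheticDataset, leaf_state: str) -> float:
    """Spearman correlation of recovered pseudotime vs true branch position.

    Restricted to ordered cells generated on the root-to-leaf branch's
    segments.
    """
    branch = set(ds.branch_cells(leaf_state))
    cells = [c for c in po.cell_ids if c in branch]
    if len(cells) < 3:
        return float("nan")
    truth = ds.true_position(cells)
    recovered = po.table.loc[cells, "pseudotime"].values
    rho = spearmanr(recovered, truth).statistic
    return float(rho)


def centroid_mst(ls: LandmarkSet) -> set[tuple[str, str]]:
    """Minimum spanning tree on pairwise Euclidean centroid distances.

    The conventional distance-based alternative to transitional-cell-count
    trimming; used only as a comparison baseline in tests.
    """
    g = nx.Graph()
    g.add_nodes_from(ls.names)
    for a, b in itertools.combinations(ls.names, 2):
        d = float(np.linalg.norm(ls.centroids[a].values - ls.centroids[b].values))
        g.add_edge(a, b, weight=d)
    mst = nx.minimum_spanning_tree(g)
    return {tuple(sorted(e)) for e in mst.edges}
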