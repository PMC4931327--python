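"""Synthetic branching single-cell expression data with known ground truth.

Cells are placed on the segments of a small state tree (e.g. a linear chain
A->B->C or a Y with a branch point).  Each state owns a block of signature
genes elevated by an effect size delta over a common baseline, in log2
units; a cell at fractional position u on segment (s1, s2) has mean
expression linearly interpolated between the two state means, plus i.i.d.
Gaussian noise in log2 space.  Values are then mapped back to a TPM-like
linear scale so that the standard log2(v + 1) transform recovers the log2
structure exactly.  Group labels mimic FACS gates: each cell is labelled
with its nearer segment endpoint.  True segment and position are recorded
for every cell, so trajectory recovery and ordering accuracy are directly
checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetPair


class TopologyError(ValueError):
    """State graph is not a tree rooted at the declared root."""


@dataclass
class TrajectoryTopology:
    """A rooted tree of cell states with per-segment cell counts.

    states : state names, in signature-block order (state i's block is
        genes [i * block_size, (i+1) * block_size)).
    edges : directed (parent, child) segments.
    cells_per_segment : cells sampled on each segment (single int applies
        to all segments).
    delta : log2 effect size of a state's signature block over baseline.
    baseline : log2-scale baseline expression of every gene.
    block_size : signature genes per state.
    """

    states: list[str]
    edges: list[tuple[str, str]]
    cells_per_segment: int | dict[tuple[str, str], int] = 100
    delta: float = 4.0
    baseline: float = 1.0
    block_size: int = 20
    root: str | None = None

    def __post_init__(self) -> None:
        if self.root is None:
            children = {c for _, c in self.edges}
            roots = [s for s in self.states if s not in children]
            if len(roots) != 1:
                raise TopologyError(f"expected exactly one root, found {roots}")
            self.root = roots[0]
        self._validate()

    def _validate(self) -> None:
        names = set(self.states)
        if len(names) != len(self.states):
            raise TopologyError("duplicate state names")
        for a, b in self.edges:
            if a not in names or b not in names:
                raise TopologyError(f"edge ({a}, {b}) uses an unknown state")
        if len(self.edges) != len(self.states) - 1:
            raise TopologyError("edge list does not form a tree")
        # reachability from root
        adj: dict[str, list[str]] = {s: [] for s in self.states}
        for a, b in self.edges:
            adj[a].append(b)
        seen = {self.root}
        stack = [self.root]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt in seen:
                    raise TopologyError("cycle detected")
                seen.add(nxt)
                stack.append(nxt)
        if seen != names:
            raise TopologyError(f"states unreachable from root: {names - seen}")

    def n_cells_on(self, edge: tuple[str, str]) -> int:
        if isinstance(self.cells_per_segment, dict):
            return self.cells_per_segment[edge]
        return self.cells_per_segment

    def undirected_edge_set(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.edges}


@dataclass
class SyntheticDataset:
    """Simulated linear-scale expression with ground truth."""

    expression: ExpressionMatrix  # linear scale
    annotation: pd.Series  # cell -> nearer-endpoint state label
    truth: pd.DataFrame  # cell-indexed: segment_parent, segment_child, u
    topology: TrajectoryTopology
    seed: int

    def branch_cells(self, leaf: str) -> list[str]:
        """Cells on the root -> leaf branch, in true pseudotime order."""
        path = self.topology_path(leaf)
        segs = list(zip(path, path[1:]))
        t = self.truth
        rows = []
        for depth, (a, b) in enumerate(segs):
            sel = t[(t["segment_parent"] == a) & (t["segment_child"] == b)]
            for cell, u in sel["u"].items():
                rows.append((depth + u, cell))
        rows.sort()
        return [c for _, c in rows]

    def topology_path(self, leaf: str) -> list[str]:
        parent = {b: a for a, b in self.topology.edges}
        path = [leaf]
        while path[-1] != self.topology.root:
            path.append(parent[path[-1]])
        return path[::-1]

    def true_position(self, cells: list[str]) -> np.ndarray:
        """Depth + u pseudotime for cells (depth = segment index from root)."""
        depth = {}
        for a, b in self.topology.edges:
            d = len(self.topology_path(b)) - 2
            depth[(a, b)] = d
        t = self.truth.loc[cells]
        return np.array(
            [
                depth[(row["segment_parent"], row["segment_child"])] + row["u"]
                for _, row in t.iterrows()
            ]
        )


def state_means(topology: TrajectoryTopology, n_genes: int) -> pd.DataFrame:
    """Log2-scale mean expression vector per state (genes x states)."""
    need = len(topology.states) * topology.block_size
    if n_genes < need:
        raise ValueError(
            f"n_genes={n_genes} too small for {len(topology.states)} states "
            f"x block_size={topology.block_size}"
        )
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    means = np.full((n_genes, len(topology.states)), topology.baseline)
    for i, _state in enumerate(topology.states):
        lo = i * topology.block_size
        means[lo : lo + topology.block_size, i] += topology.delta
    return pd.DataFrame(means, index=gene_ids, columns=topology.states)


def signature_block(topology: TrajectoryTopology, n_genes: int, state: str) -> set[str]:
    means = state_means(topology, n_genes)
    return set(means.index[(means[state] - topology.baseline) > 0])


def simulate_branching(
    topology: TrajectoryTopology,
    n_genes: int = 100,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticDataset:
    """Sample cells along the topology's segments.

    Per segment (s1, s2), positions u ~ Uniform(0, 1); a cell's log2 mean is
    (1 - u) * mu(s1) + u * mu(s2), with N(0, noise_sd) noise per gene.  The
    linear-scale value is 2**y - 1 (clipped at 0), the inverse of
    log2(v + 1).  Fixed seed gives bit-identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    means = state_means(topology, n_genes)
    cols, labels, truth_rows, cell_ids = [], [], [], []
    for a, b in topology.edges:
        n = topology.n_cells_on((a, b))
        u = rng.uniform(0.0, 1.0, size=n)
        mu = np.outer(means[a].values, 1.0 - u) + np.outer(means[b].values, u)
        y = mu + rng.normal(0.0, noise_sd, size=mu.shape) if noise_sd > 0 else mu
        cols.append(np.clip(np.exp2(y) - 1.0, 0.0, None))
        for i in range(n):
            cell = f"{a}-{b}_{i:03d}"
            cell_ids.append(cell)
            labels.append(a if u[i] < 0.5 else b)
            truth_rows.append(
                {"cell_id": cell, "segment_parent": a, "segment_child": b, "u": u[i]}
            )
    data = pd.DataFrame(np.hstack(cols), index=means.index, columns=cell_ids)
    return SyntheticDataset(
        expression=ExpressionMatrix(data, scale="linear"),
        annotation=pd.Series(labels, index=cell_ids, name="group"),
        truth=pd.DataFrame(truth_rows).set_index("cell_id"),
        topology=topology,
        seed=seed,
    )


def attach_signatures(
    ds: SyntheticDataset, positive_state: str, negative_state: str
) -> GeneSetPair:
    """Up/down signature from two states' gene blocks (e.g. the two leaves)."""
    if positive_state == negative_state:
        raise ValueError("positive and negative states must differ")
    for s in (positive_state, negative_state):
        if s not in ds.topology.states:
            raise ValueError(f"unknown state {s!r}")
    n_genes = ds.expression.n_genes
    return GeneSetPair(
        up_genes=signature_block(ds.topology, n_genes, positive_state),
        down_genes=signature_block(ds.topology, n_genes, negative_state),
        name=f"{positive_state}_vs_{negative_state}",
    )


def y_topology(
    cells_per_segment: int = 100, delta: float = 4.0, block_size: int = 20
) -> TrajectoryTopology:
    """The canonical branching test case: A -> B, then B -> C and B -> D."""
    return TrajectoryTopology(
        states=["A", "B", "C", "D"],
        edges=[("A", "B"), ("B", "C"), ("B", "D")],
        cells_per_segment=cells_per_segment,
        delta=delta,
        block_size=block_size,
    )


def linear_topology(
    cells_per_segment: int = 100, delta: float = 4.0, block_size: int = 20
) -> TrajectoryTopology:
    """Linear chain A -> B -> C."""
    return TrajectoryTopology(
        states=["A", "B", "C"],
        edges=[("A", "B"), ("B", "C")],
        cells_per_segment=cells_per_segment,
        delta=delta,
        block_size=block_size,
    )


def write_dataset(ds: SyntheticDataset, expr_path, ann_path, truth_path) -> None:
    from .io import write_annotation, write_expression

    write_expression(ds.expression, expr_path)
    write_annotation(ds.annotation, ann_path)
    ds.truth.rename_axis("cell_id").to_csv(truth_path, sep="\t")
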