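"""Landmark designation: cluster cells, score cluster purity, pick the cut.

Cells are clustered hierarchically (Euclidean distance, Ward criterion) on
the log2 expression matrix.  The dendrogram is cut at increasing depth; at
each cut every cluster is scored for purity (Shannon diversity of its group
labels) and relative size, and clusters passing both cutoffs are designated
landmarks.  The optimal cut is where the landmark count plateaus.  A
landmark is summarised by the per-gene mean of its member cells (its
centroid) and named after the majority group label.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .io import ExpressionMatrix, ScaleError, check_annotation


@dataclass
class Dendrogram:
    """Ward merge tree over cells (scipy linkage encoding)."""

    linkage: np.ndarray
    cell_ids: list[str]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClusterSet:
    """A flat clustering of all cells into ``k`` non-empty clusters (1..k)."""

    k: int
    assignment: pd.Series  # cell_id -> cluster index in 1..k

    def members(self, index: int) -> list[str]:
        return list(self.assignment.index[self.assignment == index])


@dataclass
class LandmarkParams:
    """Cutoffs for landmark designation.

    diversity_cut : maximum Shannon diversity (natural log) for a cluster to
        count as pure; with the unnormalized convention a 50/50 two-group
        cluster (H = ln 2 ~ 0.693) fails the default cut of 0.6.
    size_cut : minimum cluster size as a fraction of all cells.
    k_range : inclusive range of dendrogram cut depths to scan.
    normalized : divide the Shannon index by ln(#groups observed in the
        whole annotation) so it lies in [0, 1].
    """

    diversity_cut: float = 0.6
    size_cut: float = 0.05
    k_range: tuple[int, int] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.diversity_cut < 0:
            raise ValueError("diversity_cut must be >= 0")
        if not 0 < self.size_cut < 1:
            raise ValueError("size_cut must be in (0, 1)")


@dataclass
class LandmarkSet:
    """Designated landmark clusters with centroids and metadata.

    ``centroids`` is a genes x landmarks DataFrame; ``membership`` maps
    cell_id -> landmark name for the member cells of landmark clusters
    (non-landmark cells are absent).
    """

    centroids: pd.DataFrame
    membership: pd.Series
    k: int | None = None
    curve: pd.Series | None = None
    params: LandmarkParams | None = None

    @property
    def names(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def n_landmarks(self) -> int:
        return self.centroids.shape[1]

    def members(self, name: str) -> list[str]:
        return list(self.membership.index[self.membership == name])


def hierarchical_cluster(m: ExpressionMatrix) -> Dendrogram:
    """Agglomerate cells with the Ward minimum-variance criterion.

    Operates on cells as observations (columns of the matrix) in Euclidean
    gene space; deterministic for a fixed input.
    """
    if m.scale != "log2":
        raise ScaleError("clustering expects the log2-transformed matrix")
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    X = np.ascontiguousarray(m.values.T, dtype=float)
    Z = sch.linkage(X, method="ward")
    return Dendrogram(Z, m.cell_ids)


def cut_dendrogram(d: Dendrogram, k: int) -> ClusterSet:
    """Cut the dendrogram into exactly ``k`` clusters (nested across k)."""
    if not 1 <= k <= d.n_cells:
        raise ValueError(f"k={k} out of range [1, {d.n_cells}]")
    labels = sch.cut_tree(d.linkage, n_clusters=k).ravel() + 1
    return ClusterSet(k, pd.Series(labels, index=d.cell_ids, name="cluster"))


def cluster_diversity(
    members: list[str], ann: pd.Series, normalized: bool = False
) -> float:
    """Shannon diversity H = -sum p_g ln p_g of group labels within a cluster.

    0 for a pure cluster; ln(#groups) for a uniform mixture.  With
    ``normalized`` the index is divided by ln of the number of groups in the
    full annotation, mapping it onto [0, 1].
    """
    if len(members) == 0:
        raise ValueError("cluster has no members")
    counts = ann.loc[list(members)].value_counts()
    p = counts.values / counts.values.sum()
    h = float(-(p * np.log(p)).sum())
    if normalized:
        n_groups = ann.nunique()
        h = h / np.log(n_groups) if n_groups > 1 else 0.0
    return h


def designate_landmarks(
    cs: ClusterSet, ann: pd.Series, params: LandmarkParams | None = None
) -> list[int]:
    """Return indices of clusters passing the purity and size cutoffs.

    Both boundaries are inclusive: diversity <= diversity_cut and
    size >= size_cut * n_cells.
    """
    params = params or LandmarkParams()
    n = len(cs.assignment)
    out = []
    for i in range(1, cs.k + 1):
        members = cs.members(i)
        if len(members) < params.size_cut * n:
            continue
        if cluster_diversity(members, ann, params.normalized) <= params.diversity_cut:
            out.append(i)
    return out


def landmark_curve(
    d: Dendrogram, ann: pd.Series, params: LandmarkParams | None = None
) -> pd.Series:
    """Landmark count at each cut depth k in ``params.k_range``."""
    params = params or LandmarkParams()
    lo, hi = params.k_range or (2, min(30, d.n_cells - 1))
    ks = range(lo, hi + 1)
    counts = [len(designate_landmarks(cut_dendrogram(d, k), ann, params)) for k in ks]
    return pd.Series(counts, index=pd.Index(ks, name="k"), name="n_landmarks")


def select_optimal_k(curve: pd.Series) -> int:
    """Smallest cut depth attaining the maximum landmark count.

    The landmark count typically rises with k, plateaus, then falls as
    clusters shrink below the size cutoff; the start of the plateau is the
    optimal cut.  If the curve is still rising at the largest k scanned, a
    warning notes that no plateau was found.
    """
    if len(curve) == 0:
        raise ValueError("empty landmark curve")
    best = int(curve.idxmax())
    if best == curve.index[-1] and (curve.diff().dropna() > 0).all():
        warnings.warn(
            "landmark count still increasing at the largest k scanned; "
            "no plateau found",
            stacklevel=2,
        )
    return best


def _letter_suffix(i: int) -> str:
    """0 -> a, 1 -> b, ..., 26 -> aa, ..."""
    letters = string.ascii_lowercase
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = letters[rem] + out
    return out


def build_landmark_set(
    m: ExpressionMatrix,
    cs: ClusterSet,
    ann: pd.Series,
    indices: list[int],
    k: int | None = None,
    curve: pd.Series | None = None,
    params: LandmarkParams | None = None,
) -> LandmarkSet:
    """Compute centroids and names for the designated landmark clusters.

    The centroid is the per-gene arithmetic mean over member cells.  Each
    landmark is named ``<majority group>_<letter>`` with letters assigned in
    cluster-index order within each majority group (majority ties broken by
    label order).
    """
    ann = check_annotation(m, ann)
    by_group: dict[str, int] = {}
    names, cols, membership = [], [], {}
    for i in sorted(indices):
        members = cs.members(i)
        if not members:
            raise ValueError(f"cluster {i} is empty")
        counts = ann.loc[members].value_counts()
        top = counts.max()
        majority = sorted(counts.index[counts == top])[0]
        suffix = _letter_suffix(by_group.get(majority, 0))
        by_group[majority] = by_group.get(majority, 0) + 1
        name = f"{majority}_{suffix}"
        names.append(name)
        cols.append(m.data[members].mean(axis=1))
        for c in members:
            membership[c] = name
    centroids = pd.concat(cols, axis=1)
    centroids.columns = names
    return LandmarkSet(
        centroids=centroids,
        membership=pd.Series(membership, name="landmark"),
        k=k if k is not None else cs.k,
        curve=curve,
        params=params,
    )


def find_landmarks(
    m: ExpressionMatrix,
    ann: pd.Series,
    params: LandmarkParams | None = None,
    k: int | None = None,
) -> LandmarkSet:
    """End-to-end landmark designation: cluster, scan cuts, pick k, build.

    ``k`` overrides the plateau rule (used e.g. for robustness re-runs at
    plateau+1/plateau+2).
    """
    params = params or LandmarkParams()
    ann = check_annotation(m, ann)
    d = hierarchical_cluster(m)
    curve = landmark_curve(d, ann, params)
    chosen = k if k is not None else select_optimal_k(curve)
    cs = cut_dendrogram(d, chosen)
    idx = designate_landmarks(cs, ann, params)
    if not idx:
        raise ValueError(f"no clusters pass the landmark cutoffs at k={chosen}")
    return build_landmark_set(m, cs, ann, idx, k=chosen, curve=curve, params=params)


def write_landmark_set(ls: LandmarkSet, membership_path, centroid_path) -> None:
    ls.membership.rename_axis("cell_id").to_csv(membership_path, sep="\t")
    ls.centroids.rename_axis("gene").to_csv(centroid_path, sep="\t")
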