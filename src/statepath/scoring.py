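"""Cell and landmark annotation: connectivity scores, markers, ANOVA.

The connectivity-map (cMAP) score measures how strongly one cell's
genome-wide expression ranking matches an up/down gene signature, using a
pair of Kolmogorov–Smirnov-style running-sum enrichment statistics.  Cells
significantly matching the signature (permutation p < alpha) are labelled
committed to the positive or negative lineage by the score's sign; the rest
are uncommitted.  Landmark-level differential expression uses per-gene
one-way ANOVA with Benjamini–Hochberg correction and post-hoc Tukey HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetPair, IdentifierError, check_annotation
from .landmarks import LandmarkSet


class CoverageError(ValueError):
    """Signature genes insufficiently covered by the expression matrix."""


@dataclass
class CommitmentScore:
    cell_id: str
    raw: float
    scaled: float
    p_value: float
    label: str  # positive-committed | negative-committed | uncommitted


def _ks_enrichment(positions: np.ndarray, n: int) -> float:
    """KS running-sum statistic for a gene set at 1-based ranked positions.

    a = max_j(j/s - V(j)/n) and b = max_j(V(j)/n - (j-1)/s) over the sorted
    positions V; the statistic is a if a > b else -b.
    """
    v = np.sort(positions)
    s = len(v)
    j = np.arange(1, s + 1)
    a = float((j / s - v / n).max())
    b = float((v / n - (j - 1) / s).max())
    return a if a > b else -b


def rank_genes(values: pd.Series) -> pd.Index:
    """Genes ranked by descending expression, ties broken by gene name."""
    order = np.lexsort((values.index.values.astype(str), -values.values))
    return values.index[order]


def cmap_score(cell_ranking: pd.Index, sig: GeneSetPair, min_overlap: int = 1) -> float:
    """Raw connectivity score of one cell against an up/down signature.

    ks_up - ks_down when the two enrichment statistics have opposite signs,
    else 0 (the signature's two halves agree on no direction).
    """
    n = len(cell_ranking)
    pos = pd.Series(np.arange(1, n + 1), index=cell_ranking)
    up = pos.index.intersection(sig.up_genes)
    down = pos.index.intersection(sig.down_genes)
    if len(up) < min_overlap or len(down) < min_overlap:
        raise CoverageError(
            f"signature overlap too small (up={len(up)}, down={len(down)}, "
            f"min_overlap={min_overlap})"
        )
    ks_up = _ks_enrichment(pos[up].values, n)
    ks_down = _ks_enrichment(pos[down].values, n)
    if ks_up * ks_down < 0:
        return ks_up - ks_down
    return 0.0


def _score_all_cells(
    ranks: np.ndarray, gene_names: np.ndarray, up_idx: np.ndarray, down_idx: np.ndarray
) -> np.ndarray:
    """Raw scores for all cells given precomputed per-cell gene positions.

    ``ranks[g, c]`` is the 1-based position of gene g in cell c's ranking.
    """
    n = ranks.shape[0]
    out = np.empty(ranks.shape[1])
    for c in range(ranks.shape[1]):
        ks_up = _ks_enrichment(ranks[up_idx, c], n)
        ks_down = _ks_enrichment(ranks[down_idx, c], n)
        out[c] = ks_up - ks_down if ks_up * ks_down < 0 else 0.0
    return out


def _gene_positions(m: ExpressionMatrix) -> np.ndarray:
    """1-based position of each gene in each cell's descending ranking."""
    genes = np.array(m.gene_ids, dtype=str)
    name_rank = np.argsort(np.argsort(genes))
    n_genes, n_cells = m.values.shape
    pos = np.empty((n_genes, n_cells), dtype=np.int64)
    for c in range(n_cells):
        order = np.lexsort((name_rank, -m.values[:, c]))
        pos[order, c] = np.arange(1, n_genes + 1)
    return pos


def cmap_permutation_test(
    m: ExpressionMatrix,
    sig: GeneSetPair,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    min_overlap: int = 1,
) -> list[CommitmentScore]:
    """Connectivity scores with permutation p-values and commitment labels.

    The null distribution per cell comes from ``n_perm`` random up/down gene
    sets of matching sizes drawn from the matrix's genes (one draw shared by
    all cells per permutation); p = (1 + #{|null| >= |raw|}) / (1 + n_perm).
    Scores are scaled to [-1, 1] by the maximum |raw| over the scored cells.
    A cell is committed when p < alpha and its raw score is non-zero, with
    the sign giving the direction.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse", stacklevel=2)
    genes = np.array(m.gene_ids, dtype=str)
    up_idx = np.flatnonzero(np.isin(genes, list(sig.up_genes)))
    down_idx = np.flatnonzero(np.isin(genes, list(sig.down_genes)))
    if len(up_idx) < min_overlap or len(down_idx) < min_overlap:
        raise CoverageError("signature genes not covered by the matrix")
    if len(up_idx) + len(down_idx) > m.n_genes:
        raise CoverageError("signature larger than the gene universe")

    pos = _gene_positions(m)
    raw = _score_all_cells(pos, genes, up_idx, down_idx)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(m.n_cells, dtype=np.int64)
    s_up, s_down = len(up_idx), len(down_idx)
    for _ in range(n_perm):
        perm = rng.choice(m.n_genes, size=s_up + s_down, replace=False)
        null = _score_all_cells(pos, genes, perm[:s_up], perm[s_up:])
        exceed += np.abs(null) >= np.abs(raw)
    p = (1 + exceed) / (1 + n_perm)

    max_abs = np.abs(raw).max()
    scaled = raw / max_abs if max_abs > 0 else raw.copy()
    out = []
    for i, cell_id in enumerate(m.cell_ids):
        if p[i] >= alpha or raw[i] == 0.0:
            label = "uncommitted"
        else:
            label = "positive-committed" if raw[i] > 0 else "negative-committed"
        out.append(
            CommitmentScore(
                cell_id=cell_id,
                raw=float(raw[i]),
                scaled=float(scaled[i]),
                p_value=float(p[i]),
                label=label,
            )
        )
    return out


def commitment_by_landmark(
    scores: list[CommitmentScore], membership: pd.Series
) -> pd.DataFrame:
    """Per-landmark proportions of the three commitment labels.

    ``membership`` maps cell_id -> landmark (or edge) name; scored cells not
    in the membership are ignored.  Rows sum to 1.
    """
    by_cell = {s.cell_id: s.label for s in scores}
    rows = {}
    for lm in sorted(membership.unique()):
        cells = membership.index[membership == lm]
        labels = [by_cell[c] for c in cells if c in by_cell]
        if not labels:
            continue
        n = len(labels)
        rows[lm] = {
            "positive-committed": labels.count("positive-committed") / n,
            "negative-committed": labels.count("negative-committed") / n,
            "uncommitted": labels.count("uncommitted") / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("landmark")


def scores_to_frame(scores: list[CommitmentScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cell_id": s.cell_id, "raw": s.raw, "scaled": s.scaled,
             "p": s.p_value, "label": s.label}
            for s in scores
        ]
    ).set_index("cell_id")


def marker_overlay(m: ExpressionMatrix, ls: LandmarkSet, gene: str) -> pd.Series:
    """Per-landmark median expression of a marker, min-max scaled to [0, 1].

    A gene with identical medians across all landmarks maps to all zeros
    (with a warning).
    """
    if gene not in m.data.index:
        raise IdentifierError(f"gene {gene!r} not in the matrix")
    medians = pd.Series(
        {lm: float(m.data.loc[gene, ls.members(lm)].median()) for lm in ls.names},
        name=gene,
    )
    span = medians.max() - medians.min()
    if span == 0:
        warnings.warn(f"marker {gene!r} is constant across landmarks", stacklevel=2)
        return medians * 0.0
    return (medians - medians.min()) / span


def group_anova(
    m: ExpressionMatrix,
    grouping: pd.Series,
    alpha: float = 0.05,
    tukey: bool = True,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA across groups with BH correction.

    Returns a gene-indexed table with per-group means, F, p, adjusted p and
    — for genes passing the BH threshold, when ``tukey`` — Tukey-HSD
    adjusted p-values and log2 fold changes (differences of group means on
    the log2 scale) for each group pair.  Constant genes get F = 0, p = 1.
    Groups with fewer than 2 cells are rejected.
    """
    grouping = check_annotation(m, grouping)
    groups = sorted(grouping.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    blocks = []
    for g in groups:
        cells = grouping.index[grouping == g]
        if len(cells) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        blocks.append(m.data[cells].values.T)  # cells x genes

    with np.errstate(invalid="ignore", divide="ignore"):
        res = f_oneway(*blocks, axis=0)
    F = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # constant (or within-group-constant, between-equal) genes: define F=0, p=1
    bad = ~np.isfinite(F)
    F[bad] = 0.0
    p[bad] = 1.0
    adj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame({"F": F, "p": p, "adj_p": adj}, index=m.data.index)
    for g, block in zip(groups, blocks):
        table[f"mean_{g}"] = block.mean(axis=0)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            table[f"log2fc_{b}_vs_{a}"] = table[f"mean_{b}"] - table[f"mean_{a}"]

    if tukey:
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                table[f"tukey_p_{b}_vs_{a}"] = np.nan
        labels = grouping.loc[m.cell_ids].values
        for gene in table.index[table["adj_p"] < alpha]:
            hsd = pairwise_tukeyhsd(m.data.loc[gene, :].values, labels)
            frame = pd.DataFrame(
                hsd.summary().data[1:], columns=hsd.summary().data[0]
            )
            for _, row in frame.iterrows():
                a, b = str(row["group1"]), str(row["group2"])
                col = f"tukey_p_{b}_vs_{a}"
                if col not in table.columns:
                    col = f"tukey_p_{a}_vs_{b}"
                table.loc[gene, col] = float(row["p-adj"])
    return table
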