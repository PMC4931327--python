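"""Differential expression along a pseudo-temporal ordering.

Each gene is regressed on a cubic-spline basis of the pseudotime rank
(Gaussian errors on log2 expression) and compared with an intercept-only
null by a likelihood-ratio test; p-values are BH-adjusted across genes.
Significant genes are grouped into "waves" by hierarchically clustering
their z-scored fitted trends, and per-wave trends are lowess-smoothed mean
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from patsy import dmatrix
from scipy.stats import chi2
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .ordering import PathOrdering


@dataclass
class PseudotimeDEResult:
    """Per-gene smooth-trend test results along one ordering.

    ``table``: gene-indexed (statistic, p, adj_p, significant);
    ``fitted``: genes x ordered-cells fitted smooth values;
    ``pseudotime``: the covariate actually used (rank or arc length).
    """

    table: pd.DataFrame
    fitted: pd.DataFrame
    pseudotime: pd.Series
    df: int
    alpha: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


@dataclass
class GeneWaveClusters:
    """Wave assignment of significant genes plus smoothed cluster trends."""

    assignment: pd.Series  # gene -> cluster index in 1..k
    trends: pd.DataFrame  # ordered cells x clusters, lowess-smoothed means
    k: int


def _spline_basis(x: np.ndarray, df: int, basis: str = "bs") -> np.ndarray:
    """Design matrix (with intercept) for a spline smooth of x.

    ``bs`` — cubic B-splines with ``df`` degrees of freedom (at df = 3 this
    is exactly the cubic polynomial space, so noise-free polynomials of
    degree <= 3 are reproduced); ``cr`` — natural cubic regression splines.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if basis == "bs":
        if df < 3:
            # low-df fallback: plain polynomial basis of that degree
            B = np.vander(x, df + 1, increasing=True)[:, 1:]
        else:
            B = np.asarray(dmatrix(f"bs(x, df={df}) - 1", {"x": x}))
    elif basis == "cr":
        B = np.asarray(dmatrix(f"cr(x, df={df}) - 1", {"x": x}))
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return np.column_stack([np.ones(len(x)), B])


def _covariate(ordering: PathOrdering, covariate: str) -> np.ndarray:
    if covariate == "rank":
        return ordering.table["rank"].values.astype(float)
    if covariate == "arclength":
        return ordering.table["pseudotime"].values.astype(float)
    raise ValueError(f"unknown covariate {covariate!r}")


def _lrt_matrix(
    Y: np.ndarray, x: np.ndarray, df: int, basis: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Gaussian LRT of spline vs intercept for genes in rows of Y.

    Returns (statistic, p, fitted).  statistic = n * ln(RSS0 / RSS1), chi2
    with ``df`` degrees of freedom (the extra spline columns).
    """
    n = Y.shape[1]
    if len(np.unique(x)) < 2:
        raise ValueError("pseudotime covariate is constant")
    X = _spline_basis(x, df, basis)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    rss1 = ((Y - fitted) ** 2).sum(axis=1)
    rss0 = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    k = X.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(rss0 / rss1)
    stat[np.isnan(stat)] = 0.0  # constant genes: both RSS are 0
    stat = np.maximum(stat, 0.0)  # perfect fits keep +inf -> p = 0
    p = chi2.sf(stat, k)
    return stat, p, fitted


def pseudotime_lrt(
    expr: np.ndarray | pd.Series,
    ordering: PathOrdering,
    df: int = 3,
    covariate: str = "rank",
    basis: str = "bs",
) -> tuple[float, float]:
    """Likelihood-ratio test of one gene's smooth pseudotime trend.

    ``expr`` holds the gene's values for the ordering's cells, in ordering
    order.  Returns (statistic, p).
    """
    y = np.asarray(expr, dtype=float)[None, :]
    n = y.shape[1]
    if n < 10:
        raise ValueError("need at least 10 ordered cells")
    x = _covariate(ordering, covariate)
    if len(x) != n:
        raise ValueError("expression length does not match the ordering")
    stat, p, _ = _lrt_matrix(y, x, df, basis)
    return float(stat[0]), float(p[0])


def pseudotime_de_scan(
    m: ExpressionMatrix,
    ordering: PathOrdering,
    alpha: float = 0.05,
    df: int = 3,
    covariate: str = "rank",
    basis: str = "bs",
) -> PseudotimeDEResult:
    """Smooth-trend LRT for every gene along the ordering, BH-adjusted."""
    cells = ordering.cell_ids
    if len(cells) < 10:
        raise ValueError("need at least 10 ordered cells")
    Y = m.data[cells].values
    x = _covariate(ordering, covariate)
    stat, p, fitted = _lrt_matrix(Y, x, df, basis)
    adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"statistic": stat, "p": p, "adj_p": adj, "significant": adj < alpha},
        index=m.data.index,
    )
    fitted_df = pd.DataFrame(fitted, index=m.data.index, columns=cells)
    return PseudotimeDEResult(
        table=table,
        fitted=fitted_df,
        pseudotime=pd.Series(x, index=cells, name="pseudotime"),
        df=df,
        alpha=alpha,
    )


def cluster_waves(
    res: PseudotimeDEResult, k: int, lowess_frac: float = 0.75
) -> GeneWaveClusters:
    """Group significant genes into k waves by their fitted trend shapes.

    Fitted profiles are z-scored per gene, clustered hierarchically
    (Euclidean, Ward) and the tree cut into k clusters.  Genes are processed
    in sorted-name order so the result is independent of input order.
    Cluster trends are lowess smooths of the member-mean z-profiles.
    """
    genes = sorted(res.significant_genes)
    if k < 1 or k > len(genes):
        raise ValueError(f"k={k} outside [1, {len(genes)}] significant genes")
    prof = res.fitted.loc[genes].values
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (prof - mu) / sd
    if k == 1 or len(genes) == 1:
        labels = np.ones(len(genes), dtype=int)
    else:
        Z = sch.linkage(z, method="ward")
        labels = sch.cut_tree(Z, n_clusters=k).ravel()
        # relabel 1..k by first occurrence in gene-name order
        seen: dict[int, int] = {}
        for lab in labels:
            if lab not in seen:
                seen[lab] = len(seen) + 1
        labels = np.array([seen[lab] for lab in labels])
    assignment = pd.Series(labels, index=pd.Index(genes, name="gene"), name="cluster")

    x = res.pseudotime.values
    trends = {}
    for c in range(1, k + 1):
        mean_prof = z[labels == c].mean(axis=0)
        sm = lowess(mean_prof, x, frac=lowess_frac, return_sorted=False)
        trends[c] = sm
    trends_df = pd.DataFrame(trends, index=res.pseudotime.index)
    return GeneWaveClusters(assignment=assignment, trends=trends_df, k=k)


def write_de_results(
    res: PseudotimeDEResult, clusters: GeneWaveClusters | None, table_path, trend_path=None
) -> None:
    table = res.table.copy()
    if clusters is not None:
        table["cluster"] = clusters.assignment.reindex(table.index)
    table.rename_axis("gene").to_csv(table_path, sep="\t")
    if clusters is not None and trend_path is not None:
        out = clusters.trends.copy()
        out.insert(0, "pseudotime", res.pseudotime.values)
        out.rename_axis("cell_id").to_csv(trend_path, sep="\t")
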