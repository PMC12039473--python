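"""Differential-expression thresholding, clustering and expression IFN score.

The differential-expression model fit itself is upstream; this module
selects genes from its results table (|log2FC| > 1 and adjusted
p < 0.001, both strict), extracts the gene set shared between
top-ranked pathway terms, clusters samples hierarchically on that set
(Ward linkage on z-scored expression), regresses cluster-mean disease
activity on cluster-mean expression, and computes the expression-based
type I interferon score (geometric mean of the interferon-response
genes divided by 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import linregress


def select_de_genes(
    table: pd.DataFrame,
    log2fc_min: float = 1.0,
    padj_max: float = 0.001,
) -> set[str]:
    """Select differentially expressed genes by strict fold-change and padj.

    A gene passes with log2FC > ``log2fc_min`` or < -``log2fc_min``
    (boundary excluded) and padj < ``padj_max`` (boundary excluded).
    Records with missing padj are excluded.  Order-invariant and
    idempotent by construction (a pure predicate scan).
    """
    ok = table["padj"].notna() & table["log2fc"].notna()
    fc = table["log2fc"].to_numpy(dtype=float)
    padj = table["padj"].to_numpy(dtype=float)
    mask = ok.to_numpy() & ((fc > log2fc_min) | (fc < -log2fc_min)) & (padj < padj_max)
    return set(table.loc[mask, "gene"])


def shared_pathway_genes(
    top_sets: Sequence[set[str]],
    de_genes: set[str],
    mode: str = "union",
) -> set[str]:
    """Genes shared between top-ranked pathway terms, restricted to DE genes.

    Modes:

    - ``union`` (default): union of the sets, intersected with the DE set.
    - ``at_least_2``: genes in >= 2 of the sets, intersected with DE.
    - ``intersection``: strict n-way intersection, intersected with DE.
    """
    sets = [set(s) for s in top_sets]
    if not sets or any(len(s) == 0 for s in sets):
        raise ValueError("pathway gene sets must be non-empty")
    if mode == "union":
        pool = set().union(*sets)
    elif mode == "at_least_2":
        pool = {g for g in set().union(*sets) if sum(g in s for s in sets) >= 2}
    elif mode == "intersection":
        pool = set.intersection(*sets)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pool & set(de_genes)


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene (row) across samples; zero-variance rows become 0."""
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0)
    z = expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def cluster_samples(
    expr: pd.DataFrame,
    n_clusters: int,
    method: str = "ward",
) -> pd.Series:
    """Agglomerative sample clustering on z-scored expression profiles.

    ``expr`` is genes x samples restricted to the gene set of interest.
    Columns are ordered by sample id before linkage so the partition is
    invariant to input column order.  Returns integer labels (1-based)
    indexed by sample id.
    """
    if n_clusters > expr.shape[1]:
        raise ValueError(
            f"n_clusters {n_clusters} > {expr.shape[1]} samples"
        )
    expr = expr[sorted(expr.columns)]
    z = zscore_genes(expr)
    link = linkage(z.to_numpy().T, method=method)
    labels = fcluster(link, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=expr.columns, name="cluster")


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares fit of y on x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple OLS with a two-sided slope p-value (t test, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    fit = linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def cluster_sas_regression(
    labels: pd.Series,
    expr: pd.DataFrame,
    sas: Mapping[str, float],
) -> RegressionResult:
    """Regress cluster-mean disease activity on cluster-mean expression.

    For each cluster the x coordinate is the mean over member samples
    of the per-sample mean z-scored expression, and the y coordinate is
    the mean Still Activity Score of the members.  One point per
    cluster; at least 3 clusters are required for the fit.
    """
    clusters = sorted(labels.unique())
    if len(clusters) < 3:
        raise ValueError(f"need >= 3 clusters, got {len(clusters)}")
    z = zscore_genes(expr[list(labels.index)])
    sample_score = z.mean(axis=0)  # mean z-expression per sample
    xs, ys = [], []
    for c in clusters:
        members = labels.index[labels == c]
        missing = [s for s in members if s not in sas]
        if missing:
            raise ValueError(f"samples without SAS: {missing}")
        xs.append(float(sample_score[members].mean()))
        ys.append(float(np.mean([sas[s] for s in members])))
    return ols_fit(xs, ys)


def ifn_score_expression(
    expr: pd.DataFrame,
    sample: str,
    ifn_genes: Sequence[str],
    pseudocount: float = 1.0,
) -> float:
    """Expression-based type I IFN score: geometric mean over the
    interferon-response genes divided by 10.

    A pseudocount (default 1) is added before the geometric mean so
    zero-expression genes stay finite; with ``pseudocount=0`` zeros
    propagate to a score of 0 exactly.  Missing genes are an error
    naming them.
    """
    missing = [g for g in ifn_genes if g not in expr.index]
    if missing:
        raise ValueError(f"IFN response genes missing from matrix: {missing}")
    if sample not in expr.columns:
        raise ValueError(f"sample {sample!r} not in expression matrix")
    vals = expr.loc[list(ifn_genes), sample].to_numpy(dtype=float) + pseudocount
    if (vals < 0).any():
        raise ValueError("negative expression after pseudocount")
    if (vals == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(vals))) / 10.0)


def ifn_scores_expression(
    expr: pd.DataFrame,
    ifn_genes: Sequence[str],
    samples: Iterable[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample expression IFN scores for many samples."""
    samples = list(samples) if samples is not None else list(expr.columns)
    return pd.Series(
        [ifn_score_expression(expr, s, ifn_genes, pseudocount) for s in samples],
        index=samples,
        name="ifn_score_expression",
    )
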