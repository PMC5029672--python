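"""Poor-prognosis signature analysis: merge classifier gene lists, correlate
DE lncRNAs against the signature genes across all samples, cluster the
correlation matrix (Euclidean distance, complete linkage), and extract the
positively correlated lncRNA set.

Correlations are Pearson on log-RPKM (pseudocount 0.01) pooled over every
sample regardless of group.  Extraction combines two mechanisms: the
row-dendrogram cluster with the highest mean correlation, intersected with a
per-row mean-correlation floor, so the result is reproducible from config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .expression import LOG_PSEUDOCOUNT

logger = logging.getLogger(__name__)

DEFAULT_MIN_MEAN_R = 0.3


@dataclass
class SignatureSet:
    sources: dict[str, set[str]]
    merged: set[str]
    restricted: set[str] | None = None


@dataclass
class CorrelationMatrix:
    matrix: pd.DataFrame          # rows = lncRNAs, cols = signature genes
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)
    row_clusters: pd.Series | None = None
    positive_set: set[str] = field(default_factory=set)


def read_gene_list(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.add(g)
    return out


def merge_signatures(lists: dict[str, set[str]], measured: set[str] | None = None) -> SignatureSet:
    """Union of the source lists, restricted to measured genes when an
    expression universe is given (dropped genes logged)."""
    if not any(lists.values()):
        raise ValueError("all signature lists are empty")
    merged = set().union(*lists.values())
    if measured is not None:
        dropped = merged - measured
        if dropped:
            logger.info("%d signature gene(s) not in the expression matrix, dropped", len(dropped))
        merged &= measured
    return SignatureSet(sources=lists, merged=merged)


def restrict_to_de(sig: SignatureSet, de: pd.DataFrame) -> SignatureSet:
    """Keep signature genes significant in the given DE table (the
    primary-vs-metastasis profile for the metastasis variant)."""
    restricted = {g for g in sig.merged if g in de.index and de.at[g, "significant"]}
    if not restricted:
        logger.warning("no signature gene is differentially expressed")
    sig.restricted = restricted
    return sig


def correlation_matrix(
    expr: pd.DataFrame,
    lnc_ids: list[str],
    sig_genes: list[str],
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> CorrelationMatrix:
    """Pearson correlation of each lncRNA with each signature gene over all
    samples (log10 RPKM + pseudocount); constant rows give r = 0."""
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    lnc_ids = [g for g in lnc_ids if g in expr.index]
    sig_genes = [g for g in sig_genes if g in expr.index]
    lx = np.log10(expr.loc[lnc_ids].to_numpy(dtype=float) + pseudocount)
    sx = np.log10(expr.loc[sig_genes].to_numpy(dtype=float) + pseudocount)

    def _std_rows(x):
        sd = x.std(axis=1, ddof=0)
        const = sd == 0
        if const.any():
            logger.warning("%d constant profile(s): correlations set to 0", const.sum())
        xc = x - x.mean(axis=1, keepdims=True)
        xn = xc / (np.where(const, 1.0, sd)[:, None] * np.sqrt(x.shape[1]))
        xn[const] = 0.0
        return xn

    c = _std_rows(lx) @ _std_rows(sx).T
    m = pd.DataFrame(np.clip(c, -1, 1), index=lnc_ids, columns=sig_genes)
    return CorrelationMatrix(matrix=m)


def cluster_matrix(cm: CorrelationMatrix, n_row_clusters: int = 10) -> CorrelationMatrix:
    """Hierarchically cluster rows and columns of the correlation matrix with
    Euclidean distance and complete linkage; stores dendrogram leaf orders
    and a flat row clustering at ``n_row_clusters``."""
    m = cm.matrix
    if m.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    zr = linkage(m.to_numpy(), method="complete", metric="euclidean")
    cm.row_order = [m.index[i] for i in leaves_list(zr)]
    if m.shape[1] >= 2:
        zc = linkage(m.to_numpy().T, method="complete", metric="euclidean")
        cm.col_order = [m.columns[i] for i in leaves_list(zc)]
    else:
        cm.col_order = list(m.columns)
    k = min(n_row_clusters, m.shape[0])
    cm.row_clusters = pd.Series(fcluster(zr, t=k, criterion="maxclust"), index=m.index)
    return cm


def extract_positive_set(
    cm: CorrelationMatrix,
    min_mean_r: float = DEFAULT_MIN_MEAN_R,
) -> set[str]:
    """Rows of every cluster whose mean correlation with the signature genes
    reaches ``min_mean_r``, further restricted to rows whose own mean
    correlation reaches it.  When all rows correlate strongly every cluster
    qualifies; when only a planted block does, only that cluster survives.
    Empty (with a warning) when nothing qualifies."""
    if cm.row_clusters is None:
        raise ValueError("cluster_matrix must run first")
    mean_r = cm.matrix.mean(axis=1)
    members: set[str] = set()
    for c in sorted(cm.row_clusters.unique()):
        idx = cm.row_clusters.index[cm.row_clusters == c]
        if mean_r[idx].mean() >= min_mean_r:
            members |= set(idx)
    out = {g for g in members if mean_r[g] >= min_mean_r}
    if not out:
        logger.warning("no lncRNA reaches mean r >= %.2f", min_mean_r)
    cm.positive_set = out
    return out
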