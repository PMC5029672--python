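"""RPKM conversion, expressed-gene tiers, and descriptive expression stats.

RPKM = count * 1e9 / (exon_model_length * library_size), with library size
taken as the per-sample column total of the provided count matrix (the true
mapped-read total is unavailable once counting is done; a sidecar vector of
library sizes can be passed instead).  Log transforms use a pseudocount of
0.01 RPKM.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

LOG_PSEUDOCOUNT = 0.01


def rpkm(
    counts: pd.DataFrame,
    ann: GenomeAnnotation,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Convert raw counts (genes x samples) to RPKM."""
    lengths = np.array([ann[g].exon_model_length for g in counts.index], dtype=float)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    else:
        library_sizes = library_sizes.reindex(counts.columns).astype(float)
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    out = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * library_sizes.to_numpy()[None, :])
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def log_rpkm(expr: pd.DataFrame, pseudocount: float = LOG_PSEUDOCOUNT) -> pd.DataFrame:
    return np.log10(expr + pseudocount)


def expressed_set(
    expr: pd.DataFrame,
    threshold: float = 0.3,
    min_samples: int = 1,
    strict: bool = False,
) -> set[str]:
    """Genes exceeding an RPKM threshold in at least ``min_samples`` samples.

    The detectable tier uses RPKM >= 0.3 (inclusive); the active tier uses
    RPKM > 1 (``strict=True``).
    """
    if threshold < 0 or min_samples < 1:
        raise ValueError("threshold must be >= 0 and min_samples >= 1")
    hit = expr > threshold if strict else expr >= threshold
    return set(expr.index[hit.sum(axis=1) >= min_samples])


def biotype_expression_test(
    expr: pd.DataFrame,
    ann: GenomeAnnotation,
    samples: pd.DataFrame | None = None,
    group: str | None = None,
    pseudocount: float = LOG_PSEUDOCOUNT,
    method: str = "asymptotic",
) -> tuple[float, float]:
    """Wilcoxon rank-sum test of lncRNA vs mRNA expression level.

    Compares per-gene mean log10(RPKM + pseudocount) between biotypes
    (within one group when given), using the normal approximation with
    continuity and tie correction.  Returns ``(W, two-sided p)``.
    """
    cols = expr.columns
    if group is not None:
        if samples is None:
            raise ValueError("samples metadata required when group is given")
        cols = samples.index[samples["group"] == group]
    m = np.log10(expr[cols] + pseudocount).mean(axis=1)
    lnc = m[[g for g in m.index if ann[g].biotype == "lncRNA"]].to_numpy()
    cod = m[[g for g in m.index if ann[g].biotype == "coding"]].to_numpy()
    if len(lnc) == 0 or len(cod) == 0:
        raise ValueError("need at least one expressed gene of each biotype")
    res = stats.mannwhitneyu(lnc, cod, alternative="two-sided", use_continuity=True, method=method)
    return float(res.statistic), float(res.pvalue)


def pca_scores(
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    n_components: int = 2,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first principal components of log expression.

    Input is log10(RPKM + pseudocount), gene-centered; returns
    ``(scores, explained_variance_ratio)``.  A constant matrix yields all-zero
    scores.  Component signs are fixed by orienting each loading vector so
    its largest-magnitude entry is positive.
    """
    if genes is not None:
        expr = expr.loc[[g for g in genes if g in expr.index]]
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    x = np.log10(expr.to_numpy(dtype=float) + pseudocount)
    x = x - x.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the samples x genes matrix
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    if s[0] == 0:
        k = min(n_components, len(s))
        scores = pd.DataFrame(
            np.zeros((expr.shape[1], k)), index=expr.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return scores, np.zeros(k)
    k = min(n_components, len(s))
    # deterministic sign: largest-|loading| gene positive
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = pd.DataFrame(
        u[:, :k] * s[:k], index=expr.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    evr = (s**2) / (s**2).sum()
    return scores, evr[:k]
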