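"""Weighted co-expression network: soft-threshold adjacency, topological
overlap, module detection, eigengenes, and module–trait correlation.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^power.  The
topological overlap TOM_ij = (sum_u a_iu*a_uj + a_ij) / (min(k_i,k_j) + 1 -
a_ij) measures shared neighborhoods; modules come from average-linkage
hierarchical clustering of 1 - TOM with a static height cut, and each module
is summarized by its eigengene — the first principal component of the
standardized member expression, oriented so members correlate positively
with it on average.  Traits enter as one-hot group indicators per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_MIN_MODULE_SIZE = 30
#: static cut height on the 1 - TOM dissimilarity scale (bounded in [0, 1]):
#: genuine co-expression merges sit well below it, while merges involving
#: unrelated transcripts concentrate just under 1
DEFAULT_CUT_HEIGHT = 0.98
DEFAULT_MERGE_CUTOFF = 0.75  # merge modules with eigengene correlation above this


@dataclass
class ModuleSet:
    """Module assignment (label 0 = unassigned), eigengenes (modules x
    samples), and the module–trait correlation table."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    trait_correlation: pd.DataFrame = field(default_factory=pd.DataFrame)
    power: int = 6
    merge_cutoff: float = DEFAULT_MERGE_CUTOFF

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def select_variable(log_expr: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k transcripts by variance of log expression across all samples;
    ties break by gene id so selection is deterministic."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(log_expr):
        raise ValueError(f"k={k} exceeds {len(log_expr)} transcripts")
    var = log_expr.var(axis=1, ddof=1)
    order = sorted(log_expr.index, key=lambda g: (-var[g], g))
    return log_expr.loc[order[:k]]


def _cor_matrix(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations; constant rows correlate at 0."""
    sd = x.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        logger.warning("%d constant transcript(s): correlations set to 0", const.sum())
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.where(const, 1.0, sd) * np.sqrt(x.shape[1])
    xn = xc / denom[:, None]
    c = xn @ xn.T
    c[const, :] = 0.0
    c[:, const] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def adjacency(log_expr: pd.DataFrame, power: int, signed: bool = False) -> np.ndarray:
    c = _cor_matrix(log_expr.to_numpy(dtype=float))
    if signed:
        a = ((1 + c) / 2.0) ** power
    else:
        a = np.abs(c) ** power
    np.fill_diagonal(a, 1.0)
    return a


def pick_power(
    log_expr: pd.DataFrame,
    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12),
    r2_target: float = 0.8,
    n_bins: int = 10,
    signed: bool = False,
) -> int:
    """Smallest candidate power whose connectivity distribution fits a
    scale-free law with R^2 >= ``r2_target`` (log-log regression over binned
    connectivity, negative slope required); falls back to the best-R^2 power
    with a warning.  A single candidate is returned as-is."""
    if len(log_expr) < 10:
        raise ValueError("need >= 10 transcripts to assess scale-free fit")
    if len(candidate_powers) == 1:
        p = candidate_powers[0]
        logger.info("single candidate power %d (R^2 = %.3f)", p, _scale_free_r2(log_expr, p, n_bins, signed))
        return p
    best, best_r2 = None, -np.inf
    for p in sorted(candidate_powers):
        r2 = _scale_free_r2(log_expr, p, n_bins, signed)
        if r2 > best_r2:
            best, best_r2 = p, r2
        if r2 >= r2_target:
            return p
    logger.warning("no candidate power reached R^2 >= %.2f; using %d (R^2 = %.3f)", r2_target, best, best_r2)
    return best


def _scale_free_r2(log_expr: pd.DataFrame, power: int, n_bins: int, signed: bool) -> float:
    a = adjacency(log_expr, power, signed=signed)
    k = a.sum(axis=1) - 1.0
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    # equal-width bins on k: the scale-free criterion regresses log10 p(k)
    # on log10 k, so bin frequencies must be free to vary
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    logk, logp = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        logk.append(np.log10(k[sel].mean()))
        logp.append(np.log10(sel.mean()))
    if len(logk) < 3:
        return 0.0
    slope, _inter, r, *_ = stats.linregress(logk, logp)
    return float(r**2) if slope < 0 else 0.0


def tom(log_expr: pd.DataFrame, power: int, signed: bool = False) -> pd.DataFrame:
    """Topological overlap matrix: symmetric, unit diagonal, entries in [0,1]."""
    if power < 1:
        raise ValueError("power must be >= 1")
    a = adjacency(log_expr, power, signed=signed)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    t = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(t, index=log_expr.index, columns=log_expr.index)


def detect_modules(
    tom_m: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    ``cut_height=None`` uses the absolute default 0.98 on the dissimilarity
    scale.  Clusters smaller than ``min_module_size`` become label 0
    (unassigned); surviving modules are renumbered 1..K by decreasing size
    (ties by first member id).
    """
    d = 1.0 - tom_m.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    if cut_height is None:
        cut_height = DEFAULT_CUT_HEIGHT
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom_m.index)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    relabel = {}
    ordered = sorted(keep, key=lambda c: (-sizes[c], str(labels.index[labels == c][0])))
    for new, old in enumerate(ordered, start=1):
        relabel[old] = new
    return labels.map(lambda c: relabel.get(c, 0))


def module_eigengene(log_expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module across samples, unit variance,
    oriented so the mean member correlation with the eigengene is positive."""
    eg = {}
    for mod in sorted(set(labels) - {0}):
        members = labels.index[labels == mod]
        if len(members) < 2:
            raise ValueError(f"module {mod} has fewer than 2 members")
        x = log_expr.loc[members].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        e = vt[0]
        if np.mean(xs @ e) < 0:
            e = -e
        e_sd = e.std(ddof=0)
        eg[mod] = e / (e_sd if e_sd > 0 else 1.0)
    return pd.DataFrame(eg, index=log_expr.columns).T


def merge_modules(
    log_expr: pd.DataFrame,
    labels: pd.Series,
    merge_cutoff: float = DEFAULT_MERGE_CUTOFF,
) -> pd.Series:
    """Iteratively merge the module pair with the highest eigengene
    correlation above ``merge_cutoff``, recomputing eigengenes after each
    merge, until no pair qualifies.  Idempotent at the fixed point."""
    if not (0 < merge_cutoff < 1):
        raise ValueError("merge_cutoff must be in (0, 1)")
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eg = module_eigengene(log_expr, labels)
        c = np.corrcoef(eg.to_numpy())
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= merge_cutoff:
            break
        keep_mod, drop_mod = sorted((mods[i], mods[j]))
        labels[labels == drop_mod] = keep_mod
    # renumber contiguously by size
    sizes = labels[labels != 0].value_counts()
    ordered = sorted(sizes.index, key=lambda c_: (-sizes[c_], str(labels.index[labels == c_][0])))
    relabel = {old: new for new, old in enumerate(ordered, start=1)}
    return labels.map(lambda c_: relabel.get(c_, 0))


def module_trait_cor(eigengenes: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and two-sided p, t-distribution with n-2 df) between each
    module eigengene and each one-hot group trait."""
    groups = sorted(samples["group"].unique())
    n = eigengenes.shape[1]
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        for g in groups:
            t_vec = (samples["group"].reindex(eigengenes.columns) == g).to_numpy(dtype=float)
            if e.std() == 0 or t_vec.std() == 0:
                logger.warning("constant eigengene or trait; r set to 0")
                r, p = 0.0, 1.0
            else:
                r = float(np.corrcoef(e, t_vec)[0, 1])
                r = max(min(r, 1.0), -1.0)
                if abs(r) == 1.0:
                    p = 0.0
                else:
                    tstat = r * np.sqrt((n - 2) / (1 - r**2))
                    p = float(2 * stats.t.sf(abs(tstat), df=n - 2))
            rows.append((mod, g, r, p))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p"]).set_index(["module", "trait"])


def build_network(
    log_expr: pd.DataFrame,
    samples: pd.DataFrame,
    n_variable: int | None = None,
    power: int | None = None,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = None,
    merge_cutoff: float = DEFAULT_MERGE_CUTOFF,
    signed: bool = False,
) -> ModuleSet:
    """Full module pipeline: variable selection -> power -> TOM -> modules ->
    merge -> eigengenes -> trait correlation."""
    sub = select_variable(log_expr, n_variable) if n_variable else log_expr
    if power is None:
        power = pick_power(sub, signed=signed)
    t = tom(sub, power, signed=signed)
    labels = detect_modules(t, min_module_size=min_module_size, cut_height=cut_height)
    if (labels != 0).any():
        labels = merge_modules(sub, labels, merge_cutoff=merge_cutoff)
        eg = module_eigengene(sub, labels)
        tc = module_trait_cor(eg, samples)
    else:
        eg = pd.DataFrame(columns=sub.columns)
        tc = pd.DataFrame(columns=["r", "p"])
    return ModuleSet(labels=labels, eigengenes=eg, trait_correlation=tc,
                     power=power, merge_cutoff=merge_cutoff)
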