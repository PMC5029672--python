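"""Count-based differential expression: two independent procedures and their
consensus.

The calling rule mirrors the two-tool intersection design: a gene is a
consensus call only when both an NB Wald test and a label-permutation test
flag it (FDR < 0.05, |log2FC| >= 1, i.e. fold change >= 2, inclusive) with
the same direction.  Normalization is median-of-ratios; dispersion is a
per-gene method-of-moments estimate shrunk halfway toward a mean–dispersion
trend.  FDR is Benjamini–Hochberg by default (Benjamini–Yekutieli available).
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPARISONS = ("PC-NC", "PC-MC", "MC-NC")
FDR_CUT = 0.05
LFC_CUT = 1.0  # fold change >= 2, inclusive
_P_FLOOR = 1e-300  # keep p in the open-bottom interval (0, 1]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Ratios are taken to the geometric-mean pseudo-reference over genes
    positive in all samples; when no such gene exists, falls back to
    library-size ratios with a warning.
    """
    x = counts.to_numpy(dtype=float)
    if (x.sum(axis=0) == 0).any():
        bad = counts.columns[x.sum(axis=0) == 0]
        raise ValueError(f"sample(s) with all-zero counts: {list(bad)}")
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        logger.warning("no gene positive in all samples; using library-size factors")
        sf = x.sum(axis=0)
    else:
        logref = np.log(x[allpos]).mean(axis=1)
        sf = np.exp(np.median(np.log(x[allpos]) - logref[:, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _normalized(counts: pd.DataFrame, sf: pd.Series | None = None) -> np.ndarray:
    if sf is None:
        sf = size_factors(counts)
    return counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]


def _trended_dispersion(mean: np.ndarray, disp_raw: np.ndarray) -> np.ndarray:
    """Fit disp ~ a0 + a1/mean on genes with usable raw estimates, then shrink
    raw estimates halfway toward the trend (weight 0.5)."""
    ok = (mean > 0) & (disp_raw > 1e-8)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
        coef, *_ = np.linalg.lstsq(A, disp_raw[ok], rcond=None)
        a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    else:
        a0, a1 = max(np.median(disp_raw[ok]) if ok.any() else 0.1, 1e-8), 0.0
    trend = a0 + a1 / np.maximum(mean, 1e-8)
    disp = 0.5 * np.maximum(disp_raw, 0.0) + 0.5 * trend
    return np.maximum(disp, 1e-8)


def de_test_nb(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group A vs group B on normalized counts.

    log2FC (A over B) uses a 0.5 pseudocount on normalized group means; the
    Wald standard error comes from the NB variance mu + disp*mu^2 via the
    delta method.  All-zero genes get (log2fc=0, p=1).  Returns a DataFrame
    with columns log2fc, p.
    """
    for grp, name in ((group_a, "A"), (group_b, "B")):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs >= 2 samples")
    sub = counts[list(group_a) + list(group_b)]
    sf = size_factors(sub) if sf is None else sf.reindex(sub.columns)
    x = _normalized(sub, sf)
    na, nb = len(group_a), len(group_b)
    xa, xb = x[:, :na], x[:, na:]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)

    # moments dispersion pooled across the two groups
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    pooled_mean = (na * ma + nb * mb) / (na + nb)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = np.where(pooled_mean > 0, (pooled_var - pooled_mean) / pooled_mean**2, 0.0)
    disp = _trended_dispersion(pooled_mean, disp_raw)

    log2fc = np.log2((ma + 0.5) / (mb + 0.5))
    # delta-method variance of log2 of a group mean, with the pseudocount mean
    var_a = (1.0 / (ma + 0.5) + disp) / (na * np.log(2) ** 2)
    var_b = (1.0 / (mb + 0.5) + disp) / (nb * np.log(2) ** 2)
    se = np.sqrt(var_a + var_b)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    zero = (ma == 0) & (mb == 0)
    log2fc[zero] = 0.0
    p[zero] = 1.0
    p = np.clip(p, _P_FLOOR, 1.0)
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=counts.index)


def de_test_perm(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    n_perm: int = 5000,
    seed: int = 0,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Permutation test on the normalized log2 group-mean ratio.

    Two-sided tail probability of |T| under random label exchanges.  When
    the design admits no more than ``n_perm`` distinct assignments the test
    enumerates all of them (p = tail count / total, the identity included);
    otherwise it samples ``n_perm`` permutations with the +1 correction.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sub = counts[list(group_a) + list(group_b)]
    sf = size_factors(sub) if sf is None else sf.reindex(sub.columns)
    x = _normalized(sub, sf)
    na, nb = len(group_a), len(group_b)
    n = na + nb
    logx = np.log2(x + 0.5)

    def stat(idx_a: np.ndarray) -> np.ndarray:
        in_a = np.zeros(n, dtype=bool)
        in_a[idx_a] = True
        return logx[:, in_a].mean(axis=1) - logx[:, ~in_a].mean(axis=1)

    obs = stat(np.arange(na))
    n_distinct = math.comb(n, na)
    if n_distinct <= n_perm:
        perms = [np.array(c) for c in itertools.combinations(range(n), na)]
        tail = np.zeros(len(obs))
        for c in perms:
            tail += np.abs(stat(c)) >= np.abs(obs) - 1e-12
        p = tail / len(perms)
    else:
        rng = np.random.default_rng(seed)
        tail = np.zeros(len(obs))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            tail += np.abs(stat(perm[:na])) >= np.abs(obs) - 1e-12
        p = (tail + 1.0) / (n_perm + 1.0)
    p = np.clip(p, _P_FLOOR, 1.0)
    return pd.DataFrame({"log2fc": obs, "p": p}, index=counts.index)


def bh_adjust(p: np.ndarray | pd.Series, method: str = "bh") -> np.ndarray:
    """Step-up FDR adjustment (Benjamini–Hochberg, or ``method='by'`` for
    Benjamini–Yekutieli); order-equivariant with monotonicity enforcement."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("p must be a non-empty 1-d vector")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p values must lie in (0, 1]")
    m = len(arr)
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    if method == "by":
        ranked = ranked * np.sum(1.0 / np.arange(1, m + 1))
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


def _finalize(res: pd.DataFrame, fdr_method: str) -> pd.DataFrame:
    res = res.copy()
    res["fdr"] = bh_adjust(res["p"].to_numpy(), method=fdr_method)
    res["significant"] = (res["fdr"] < FDR_CUT) & (res["log2fc"].abs() >= LFC_CUT)
    res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
    return res


def de_comparison(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    comparison: str,
    n_perm: int = 5000,
    seed: int = 0,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Run both procedures for one pairwise comparison and intersect them.

    ``comparison`` is "A-B" with A, B group names; log2FC is A over B.
    Returns per gene: log2fc, p_nb, p_perm, fdr (NB), significant
    (consensus), direction.
    """
    a, b = comparison.split("-")
    ga = list(samples.index[samples["group"] == a])
    gb = list(samples.index[samples["group"] == b])
    sub = counts[ga + gb]
    sf = size_factors(sub)
    nb_res = _finalize(de_test_nb(counts, ga, gb, sf=sf), fdr_method)
    pm_res = _finalize(de_test_perm(counts, ga, gb, n_perm=n_perm, seed=seed, sf=sf), fdr_method)
    return consensus_de(nb_res, pm_res)


def consensus_de(res_nb: pd.DataFrame, res_perm: pd.DataFrame) -> pd.DataFrame:
    """Intersect two finalized DE tables: significant only when both call the
    gene with the same direction; reported log2fc/fdr come from the NB test."""
    if not res_nb.index.equals(res_perm.index):
        missing = res_nb.index.symmetric_difference(res_perm.index)
        raise ValueError(f"gene universes differ, e.g. {list(missing[:5])}")
    out = pd.DataFrame(
        {
            "log2fc": res_nb["log2fc"],
            "p_nb": res_nb["p"],
            "p_perm": res_perm["p"],
            "fdr": res_nb["fdr"],
            "direction": res_nb["direction"],
        },
        index=res_nb.index,
    )
    out["significant"] = (
        res_nb["significant"]
        & res_perm["significant"]
        & (res_nb["direction"] == res_perm["direction"])
    )
    return out


def de_all_comparisons(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Consensus DE tables for the three pairwise comparisons."""
    return {
        comp: de_comparison(counts, samples, comp, n_perm=n_perm, seed=seed + i)
        for i, comp in enumerate(COMPARISONS)
    }


def significant_set(res: pd.DataFrame) -> set[str]:
    return set(res.index[res["significant"]])
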