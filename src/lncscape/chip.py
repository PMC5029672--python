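"""Promoter histone-mark analysis from windowed ChIP read counts.

Three steps: (1) a strand-oriented aggregate signal profile around gene
TSSs; (2) differential windows between tumor and normal by a per-window
G-test (likelihood ratio of equal library-normalized rates) with BH
correction, adjacent same-direction significant windows merged into regions
called at FDR < 0.05 and fold change > 4 (strict); (3) linkage of regions to
differentially expressed lncRNA promoters (TSS +/- 3 kb) and the Pearson
correlation between region and lncRNA log2 fold changes — the
direction-consistency statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .de import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_FLANK = 3000
DEFAULT_FDR_CUT = 0.05
DEFAULT_FC_CUT = 4.0  # strict: |fold| must exceed 4


@dataclass(frozen=True)
class DifferentialRegion:
    chrom: str
    start: int
    end: int
    log2fc: float
    fdr: float

    @property
    def direction(self) -> str:
        return "gain" if self.log2fc > 0 else "loss"


@dataclass
class RegionLncLink:
    region: DifferentialRegion
    lnc_id: str
    region_log2fc: float
    lnc_log2fc: float

    @property
    def concordant(self) -> bool:
        return (self.region_log2fc > 0) == (self.lnc_log2fc > 0)


def _check_grid(tumor: pd.DataFrame, normal: pd.DataFrame) -> None:
    key = ["chrom", "start", "end"]
    if len(tumor) != len(normal) or not tumor[key].reset_index(drop=True).equals(
        normal[key].reset_index(drop=True)
    ):
        raise ValueError("tumor and normal window grids differ")


def tss_profile(
    windows: pd.DataFrame,
    tss_list: list[tuple[str, int, str]],
    flank: int = 3000,
    n_bins: int = 61,
) -> np.ndarray:
    """Average library-normalized signal in ``n_bins`` over [TSS-flank,
    TSS+flank), center bin on the TSS; minus-strand profiles are reversed so
    upstream is always left.  ``tss_list`` holds (chrom, pos, strand)."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    if n_bins % 2 == 0:
        raise ValueError("n_bins must be odd so the center bin sits on the TSS")
    if not tss_list:
        raise ValueError("empty TSS list")
    lib = float(windows["count"].sum())
    if lib <= 0:
        raise ValueError("empty signal")
    width = int(windows["end"].iloc[0] - windows["start"].iloc[0])
    # per-chromosome dense per-window normalized signal (per-bp rate)
    per_chrom: dict[str, np.ndarray] = {}
    starts0: dict[str, int] = {}
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts0[chrom] = int(sub["start"].iloc[0])
        per_chrom[chrom] = sub["count"].to_numpy(dtype=float) / (lib / 1e6) / width
    bin_w = 2 * flank / n_bins
    prof = np.zeros(n_bins)
    used = 0
    for chrom, pos, strand in tss_list:
        sig = per_chrom.get(chrom)
        if sig is None:
            continue
        centers = pos - flank + (np.arange(n_bins) + 0.5) * bin_w
        idx = ((centers - starts0[chrom]) // width).astype(int)
        ok = (idx >= 0) & (idx < len(sig))
        vals = np.zeros(n_bins)
        vals[ok] = sig[idx[ok]]
        if strand == "-":
            vals = vals[::-1]
        prof += vals
        used += 1
    if used == 0:
        raise ValueError("no TSS fell on the window grid")
    return prof / used


def differential_windows(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    fdr_cut: float = DEFAULT_FDR_CUT,
    fc_cut: float = DEFAULT_FC_CUT,
) -> list[DifferentialRegion]:
    """Per-window G-test of equal normalized rates, BH-corrected; adjacent
    significant windows with the same direction merge into one region.
    Regions must satisfy fdr < fdr_cut and |fold change| > fc_cut (strict);
    region log2fc uses a +1 pseudocount on summed normalized counts."""
    _check_grid(tumor, normal)
    t = tumor["count"].to_numpy(dtype=float)
    n = normal["count"].to_numpy(dtype=float)
    lt, ln = t.sum(), n.sum()
    if lt <= 0 or ln <= 0:
        raise ValueError("a condition has zero total signal")
    tot = t + n
    with np.errstate(divide="ignore", invalid="ignore"):
        et = tot * lt / (lt + ln)
        en = tot * ln / (lt + ln)
        g = 2.0 * (
            np.where(t > 0, t * np.log(t / et), 0.0)
            + np.where(n > 0, n * np.log(n / en), 0.0)
        )
    g = np.maximum(g, 0.0)
    p = np.clip(stats.chi2.sf(g, df=1), 1e-300, 1.0)
    p[tot == 0] = 1.0
    fdr = bh_adjust(p)
    lib_ratio = ln / lt
    log2fc_win = np.log2((t * lib_ratio + 1.0) / (n + 1.0))
    sig = (fdr < fdr_cut) & (np.abs(log2fc_win) > np.log2(fc_cut))

    regions: list[DifferentialRegion] = []
    chroms = tumor["chrom"].to_numpy()
    starts = tumor["start"].to_numpy()
    ends = tumor["end"].to_numpy()
    i, m = 0, len(t)
    while i < m:
        if not sig[i]:
            i += 1
            continue
        j = i
        up = log2fc_win[i] > 0
        while (
            j + 1 < m
            and sig[j + 1]
            and (log2fc_win[j + 1] > 0) == up
            and chroms[j + 1] == chroms[i]
            and starts[j + 1] == ends[j]
        ):
            j += 1
        tt, nn = t[i : j + 1].sum(), n[i : j + 1].sum()
        lfc = float(np.log2((tt * lib_ratio + 1.0) / (nn + 1.0)))
        if abs(lfc) > np.log2(fc_cut):
            regions.append(
                DifferentialRegion(
                    chrom=str(chroms[i]), start=int(starts[i]), end=int(ends[j]),
                    log2fc=lfc, fdr=float(fdr[i : j + 1].min()),
                )
            )
        i = j + 1
    return regions


def link_regions(
    regions: list[DifferentialRegion],
    de_lnc: pd.DataFrame,
    ann: GenomeAnnotation,
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
) -> list[RegionLncLink]:
    """One link per (region, lncRNA) where the region overlaps the lncRNA
    promoter window [TSS - flank, TSS + flank) and the lncRNA is DE."""
    if promoter_flank <= 0:
        raise ValueError("promoter_flank must be positive")
    de_ids = [
        g for g in de_lnc.index[de_lnc["significant"]]
        if g in ann and ann[g].biotype == "lncRNA"
    ]
    links = []
    for r in regions:
        for g in de_ids:
            rec = ann[g]
            if rec.chrom != r.chrom:
                continue
            lo, hi = rec.tss - promoter_flank, rec.tss + promoter_flank
            if r.start < hi and lo < r.end:  # half-open overlap
                links.append(
                    RegionLncLink(
                        region=r, lnc_id=g,
                        region_log2fc=r.log2fc,
                        lnc_log2fc=float(de_lnc.at[g, "log2fc"]),
                    )
                )
    return links


def direction_consistency(links: list[RegionLncLink]) -> tuple[float, float]:
    """Pearson r (and two-sided p, t-distribution, n-2 df) between region and
    lncRNA log2 fold changes over all links."""
    if len(links) < 3:
        raise ValueError("need >= 3 links for a correlation")
    x = np.array([l.region_log2fc for l in links])
    y = np.array([l.lnc_log2fc for l in links])
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(links)
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(tstat), df=n - 2))


def regions_table(regions: list[DifferentialRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.direction, r.log2fc, r.fdr) for r in regions],
        columns=["chrom", "start", "end", "direction", "log2fc", "fdr"],
    )


def links_table(links: list[RegionLncLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (l.region.chrom, l.region.start, l.region.end, l.lnc_id,
             l.region_log2fc, l.lnc_log2fc, l.concordant)
            for l in links
        ],
        columns=["chrom", "start", "end", "lnc_id", "region_log2fc", "lnc_log2fc", "concordant"],
    )
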