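"""Cis lncRNA–mRNA pair scan: each DE lncRNA is paired with its nearest
protein-coding gene; the pair is kept when that mRNA is itself DE and both
members clear an expression filter.  A pair is "co-regulated" when both
members are significant in at least two of the three pairwise comparisons
(direction concordance is recorded but not required).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .annotation import GenomeAnnotation
from .de import COMPARISONS, significant_set

logger = logging.getLogger(__name__)

DEFAULT_MIN_RPKM = 1.0  # mean RPKM in >= 1 group (the "active" expression tier)


@dataclass
class CisPair:
    lnc_id: str
    mrna_id: str
    distance: int
    lnc_de: dict[str, str]   # comparison -> direction, significant only
    mrna_de: dict[str, str]
    coregulated: bool = False

    @property
    def concordant(self) -> bool:
        shared = set(self.lnc_de) & set(self.mrna_de)
        return bool(shared) and all(self.lnc_de[c] == self.mrna_de[c] for c in shared)


def _de_status(de_tables: dict[str, pd.DataFrame], gene: str) -> dict[str, str]:
    out = {}
    for comp, tab in de_tables.items():
        if gene in tab.index and tab.at[gene, "significant"]:
            out[comp] = tab.at[gene, "direction"]
    return out


def _passes_expression(expr: pd.DataFrame, samples: pd.DataFrame, gene: str, min_rpkm: float) -> bool:
    if gene not in expr.index:
        return False
    by_group = expr.loc[gene].groupby(samples["group"]).mean()
    return bool((by_group >= min_rpkm).any())


def scan_cis_pairs(
    de_tables: dict[str, pd.DataFrame],
    ann: GenomeAnnotation,
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    min_rpkm: float = DEFAULT_MIN_RPKM,
    tss_based: bool = False,
) -> list[CisPair]:
    """One pair per DE lncRNA (union over the three comparisons), retained
    when the nearest coding gene is DE in >= 1 comparison and both members
    pass the expression filter.  Distance is the boundary gap by default
    (``tss_based=True`` measures from the lncRNA TSS)."""
    de_lnc = set()
    for tab in de_tables.values():
        de_lnc |= {g for g in significant_set(tab) if g in ann and ann[g].biotype == "lncRNA"}
    pairs = []
    for lnc in sorted(de_lnc):
        rec = ann[lnc]
        if tss_based:
            hit = ann.nearest_gene(rec.chrom, rec.tss, biotype_filter="coding")
        else:
            hit = ann.nearest_gene(rec.chrom, rec.start, end=rec.end, biotype_filter="coding")
        if hit is None:
            logger.info("%s: no coding gene on %s, dropped", lnc, rec.chrom)
            continue
        mrna, dist = hit
        mrna_de = _de_status(de_tables, mrna.gene_id)
        if not mrna_de:
            continue
        if not (
            _passes_expression(expr, samples, lnc, min_rpkm)
            and _passes_expression(expr, samples, mrna.gene_id, min_rpkm)
        ):
            continue
        pairs.append(
            CisPair(
                lnc_id=lnc,
                mrna_id=mrna.gene_id,
                distance=dist,
                lnc_de=_de_status(de_tables, lnc),
                mrna_de=mrna_de,
            )
        )
    return classify_coregulated(pairs)


def classify_coregulated(pairs: list[CisPair], min_comparisons: int = 2) -> list[CisPair]:
    """Flag pairs whose both members are significant in >= min_comparisons
    of the three pairwise comparisons."""
    for p in pairs:
        p.coregulated = len(p.lnc_de) >= min_comparisons and len(p.mrna_de) >= min_comparisons
    return pairs


def pairs_table(pairs: list[CisPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        row = {"lnc_id": p.lnc_id, "mrna_id": p.mrna_id, "distance": p.distance,
               "coregulated": p.coregulated, "concordant": p.concordant}
        for comp in COMPARISONS:
            row[f"lnc_{comp}"] = p.lnc_de.get(comp, "")
            row[f"mrna_{comp}"] = p.mrna_de.get(comp, "")
        rows.append(row)
    return pd.DataFrame(rows)
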