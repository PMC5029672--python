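"""Index-SNP to lncRNA proximity mapping.

Each SNP is assigned its nearest lncRNA locus; a SNP counts as "near" when
that distance is within the cutoff (10 kb by default, inclusive — a SNP at
exactly 10,000 bp counts).  SNPs on chromosomes with no lncRNA stay in the
denominator with infinite distance.  The lncRNA's DE status (PC-NC by
default) is joined onto the mapping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 10_000


@dataclass
class SNPSummary:
    n_snps: int
    n_within: int
    fraction_within: float
    n_within_de: int


def map_snps(
    snps: pd.DataFrame,
    ann: GenomeAnnotation,
    de: pd.DataFrame | None = None,
    cutoff: int = DEFAULT_CUTOFF,
) -> tuple[pd.DataFrame, SNPSummary]:
    """Map SNPs (columns snp_id, chrom, pos) to nearest lncRNA loci.

    Returns the per-SNP table (nearest_lnc, distance, within_cutoff,
    lnc_de_status) and a summary whose denominator is every input SNP,
    mapped or not.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    rows = []
    for _, s in snps.iterrows():
        hit = ann.nearest_gene(s["chrom"], int(s["pos"]), biotype_filter="lncRNA")
        if hit is None:
            logger.info("%s: no lncRNA on %s, unmapped", s["snp_id"], s["chrom"])
            rows.append((s["snp_id"], s["chrom"], int(s["pos"]), None, math.inf, False, ""))
            continue
        rec, dist = hit
        within = dist <= cutoff
        status = ""
        if de is not None and rec.gene_id in de.index and de.at[rec.gene_id, "significant"]:
            status = de.at[rec.gene_id, "direction"]
        rows.append((s["snp_id"], s["chrom"], int(s["pos"]), rec.gene_id, dist, within, status))
    table = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "nearest_lnc", "distance", "within_cutoff", "lnc_de_status"],
    )
    n = len(table)
    n_within = int(table["within_cutoff"].sum())
    n_within_de = int((table["within_cutoff"] & (table["lnc_de_status"] != "")).sum())
    summary = SNPSummary(
        n_snps=n,
        n_within=n_within,
        fraction_within=n_within / n if n else 0.0,
        n_within_de=n_within_de,
    )
    return table, summary
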