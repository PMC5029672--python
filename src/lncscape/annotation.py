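"""Gene-level genome annotation: records, I/O, and interval queries.

All coordinates are 0-based, half-open ``[start, end)`` internally.  GTF is
converted on input/output (GTF is 1-based, end-inclusive); BED is native.
Distance between a point and a gene is 0 inside the gene and the gap to the
nearest boundary otherwise; genes on different chromosomes are never
neighbors (infinite distance).  Nearest-gene ties break on smaller start,
then lexicographic gene id, so every query has one deterministic answer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Biotype = Literal["coding", "lncRNA"]

#: biotype strings accepted on input; anything else maps to "coding" with a warning
_BIOTYPE_ALIASES = {
    "coding": "coding",
    "protein_coding": "coding",
    "mRNA": "coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "lnc": "lncRNA",
}


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene locus.

    ``exon_model_length`` is the exon-union length used as the RPKM length
    denominator; for the single-exon gene models used throughout it equals
    ``end - start``.
    """

    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_model_length: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.exon_model_length == 0:
            object.__setattr__(self, "exon_model_length", self.end - self.start)
        if self.exon_model_length < 1:
            raise AnnotationError(f"{self.gene_id}: exon_model_length must be >= 1")

    @property
    def tss(self) -> int:
        """0-based position of the 5'-most transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


def tss(g: GeneRecord) -> tuple[str, int]:
    """Transcription start site as ``(chrom, position)``, strand-aware."""
    return g.chrom, g.tss


class GenomeAnnotation:
    """Collection of :class:`GeneRecord` with per-chromosome sorted indexes."""

    def __init__(self, records: Iterable[GeneRecord]):
        recs = list(records)
        ids = [r.gene_id for r in recs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate gene ids: {dupes[:5]}")
        self._records = {r.gene_id: r for r in recs}
        # per-chromosome arrays sorted by (start, gene_id) for stable tie-breaks
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        by_chrom: dict[str, list[GeneRecord]] = {}
        for r in recs:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: (r.start, r.gene_id))
            self._by_chrom[chrom] = {
                "ids": np.array([r.gene_id for r in rs], dtype=object),
                "starts": np.array([r.start for r in rs], dtype=np.int64),
                "ends": np.array([r.end for r in rs], dtype=np.int64),
                "coding": np.array([r.biotype == "coding" for r in rs], dtype=bool),
            }

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        for chrom in sorted(self._by_chrom):
            for gid in self._by_chrom[chrom]["ids"]:
                yield self._records[gid]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._records[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def records(self, biotype: str | None = None) -> list[GeneRecord]:
        return [r for r in self if biotype is None or r.biotype == biotype]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.gene_id, r.biotype, r.chrom, r.start, r.end, r.strand, r.exon_model_length)
            for r in self
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_id", "biotype", "chrom", "start", "end", "strand", "exon_model_length"],
        ).set_index("gene_id")

    # -- interval queries --------------------------------------------------

    def _candidates(self, chrom: str, biotype_filter: str | None):
        idx = self._by_chrom.get(chrom)
        if idx is None:
            return None
        if biotype_filter is None:
            mask = slice(None)
        elif biotype_filter == "coding":
            mask = idx["coding"]
        elif biotype_filter == "lncRNA":
            mask = ~idx["coding"]
        else:
            raise ValueError(f"unknown biotype filter {biotype_filter!r}")
        ids = idx["ids"][mask]
        if len(ids) == 0:
            return None
        return ids, idx["starts"][mask], idx["ends"][mask]

    def nearest_gene(
        self,
        chrom: str,
        pos: int,
        biotype_filter: str | None = None,
        end: int | None = None,
        exclude: str | None = None,
    ) -> tuple[GeneRecord, int] | None:
        """Nearest gene to a point (or to the interval ``[pos, end)``).

        Returns ``(record, distance)`` or None when the chromosome holds no
        candidate of the requested biotype.  Distance is 0 on overlap, else
        the bp gap; ties break by smaller start then gene id.
        """
        cand = self._candidates(chrom, biotype_filter)
        if cand is None:
            return None
        ids, starts, ends = cand
        if exclude is not None:
            keep = ids != exclude
            if not keep.any():
                return None
            ids, starts, ends = ids[keep], starts[keep], ends[keep]
        q_end = pos if end is None else end  # a point is a zero-width interval
        dist = np.maximum(np.maximum(starts - q_end, pos - ends), 0)
        best = np.flatnonzero(dist == dist.min())
        # sorted by (start, gene_id) already -> first hit is the tie-break winner
        i = best[0]
        return self._records[ids[i]], int(dist[i])

    def genes_within(
        self,
        chrom: str,
        pos: int,
        cutoff_bp: int,
        biotype_filter: str | None = None,
        end: int | None = None,
    ) -> list[tuple[GeneRecord, int]]:
        """All genes within ``cutoff_bp`` (inclusive) of a point or interval."""
        if cutoff_bp < 0:
            raise ValueError("cutoff_bp must be >= 0")
        cand = self._candidates(chrom, biotype_filter)
        if cand is None:
            return []
        ids, starts, ends = cand
        q_end = pos if end is None else end
        dist = np.maximum(np.maximum(starts - q_end, pos - ends), 0)
        hits = np.flatnonzero(dist <= cutoff_bp)
        return [(self._records[ids[i]], int(dist[i])) for i in hits]

    def flag_cross_biotype_overlaps(self) -> set[tuple[str, str]]:
        """All (coding, lncRNA) gene-id pairs overlapping by >= 1 bp.

        Overlap is genomic and strand-blind; the half-open convention means
        adjacent genes do not overlap.  Flagged genes carry ambiguous exonic
        territory (union-mode counting collapses their shared reads).
        """
        out: set[tuple[str, str]] = set()
        for chrom, idx in self._by_chrom.items():
            starts, ends, coding, ids = idx["starts"], idx["ends"], idx["coding"], idx["ids"]
            n = len(ids)
            for i in range(n):
                # sorted by start: scan forward until starts pass ends[i]
                for j in range(i + 1, n):
                    if starts[j] >= ends[i]:
                        break
                    if coding[i] != coding[j]:
                        c, l = (ids[i], ids[j]) if coding[i] else (ids[j], ids[i])
                        out.add((c, l))
        return out


# -- I/O -------------------------------------------------------------------


def _parse_biotype(raw: str, where: str) -> str:
    bt = _BIOTYPE_ALIASES.get(raw)
    if bt is None:
        logger.warning("%s: unknown biotype %r mapped to 'coding'", where, raw)
        return "coding"
    return bt


def read_annotation(path: str | Path, format: str | None = None) -> GenomeAnnotation:
    """Read a gene annotation from GTF or BED6 (+biotype suffix on the name).

    Format is inferred from the extension when not given.  GTF coordinates
    (1-based inclusive) are converted to the internal 0-based half-open
    convention.
    """
    path = Path(path)
    fmt = format or ("GTF" if path.suffix.lower() in (".gtf", ".gff") else "BED")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt.upper() == "GTF":
                    if len(fields) < 9:
                        raise AnnotationError("expected 9 tab-separated GTF fields")
                    chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                    if feature != "gene":
                        continue
                    attr = dict(
                        (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                        for kv in attrs.rstrip(";").split(";")
                        if kv.strip()
                    )
                    gene_id = attr["gene_id"]
                    biotype = _parse_biotype(attr.get("gene_biotype", "coding"), gene_id)
                    records.append(
                        GeneRecord(gene_id, biotype, chrom, int(start) - 1, int(end), strand)
                    )
                else:
                    if len(fields) < 6:
                        raise AnnotationError("expected >= 6 BED fields")
                    chrom, start, end, name, _score, strand = fields[:6]
                    gene_id, _, bt = name.partition("|")
                    biotype = _parse_biotype(bt or "coding", gene_id)
                    records.append(
                        GeneRecord(gene_id, biotype, chrom, int(start), int(end), strand)
                    )
            except (KeyError, ValueError, IndexError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        logger.warning("%s: empty annotation", path)
    return GenomeAnnotation(records)


def write_annotation(ann: GenomeAnnotation, path: str | Path, format: str | None = None) -> None:
    """Write GTF or BED6; deterministic record order (chrom, start, gene_id)."""
    path = Path(path)
    fmt = format or ("GTF" if path.suffix.lower() in (".gtf", ".gff") else "BED")
    with open(path, "w") as fh:
        for r in ann:
            if fmt.upper() == "GTF":
                bt = "protein_coding" if r.biotype == "coding" else "lncRNA"
                attrs = f'gene_id "{r.gene_id}"; gene_biotype "{bt}";'
                fh.write(
                    f"{r.chrom}\tlncscape\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
                )
            else:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}|{r.biotype}\t0\t{r.strand}\n"
                )


def point_gene_distance(pos: int, start: int, end: int) -> int:
    """Distance from a point to ``[start, end)``: 0 inside, gap otherwise."""
    return max(start - pos, pos - end, 0)


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp gap between two half-open intervals; 0 when they touch or overlap."""
    return max(a_start - b_end, b_start - a_end, 0)


INF_DISTANCE = math.inf
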