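import logging

import numpy as np
import pandas as pd
import pytest

from lncscape.annotation import GeneRecord, GenomeAnnotation
from lncscape.simulate import SimulationConfig, generate_annotation, generate_counts

logging.getLogger("lncscape").setLevel(logging.ERROR)


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Six genes on two chromosomes, both strands, both biotypes."""
    return GenomeAnnotation(
        [
            GeneRecord("M1", "coding", "chr1", 0, 900, "+"),
            GeneRecord("M2", "coding", "chr1", 1200, 2000, "-"),
            GeneRecord("L1", "lncRNA", "chr1", 5000, 6000, "+"),
            GeneRecord("M3", "coding", "chr2", 100, 500, "+"),
            GeneRecord("L2", "lncRNA", "chr2", 2000, 2600, "-"),
            GeneRecord("L3", "lncRNA", "chr2", 10_000, 11_000, "+"),
        ]
    )


def random_annotation(rng: np.random.Generator, n_genes: int = 40) -> GenomeAnnotation:
    """Random non-overlapping genes for oracle-equivalence fixtures."""
    records = []
    for chrom in ("chr1", "chr2"):
        pos = int(rng.integers(0, 5000))
        for i in range(n_genes // 2):
            length = int(rng.integers(200, 3000))
            start = pos + int(rng.integers(100, 8000))
            records.append(
                GeneRecord(
                    f"{chrom}G{i}",
                    "coding" if rng.random() < 0.6 else "lncRNA",
                    chrom,
                    start,
                    start + length,
                    "+" if rng.random() < 0.5 else "-",
                )
            )
            pos = start + length
    return GenomeAnnotation(records)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(
        seed=5,
        n_per_group=6,
        n_mrna=200,
        n_lnc=100,
        genome_size=8_000_000,
        n_cis_pairs=3,
        n_chip_links=0,
        frac_de=0.1,
    )
    ann = generate_annotation(cfg)
    counts, samples, truth = generate_counts(cfg, ann)
    return cfg, ann, counts, samples, truth


def brute_force_nearest(ann, chrom, pos, biotype=None, end=None):
    """Independent all-genes scan implementing the distance contract."""
    q_end = pos if end is None else end
    best = None
    for r in sorted(ann.records(biotype), key=lambda r: (r.start, r.gene_id)):
        if r.chrom != chrom:
            continue
        d = max(r.start - q_end, pos - r.end, 0)
        if best is None or d < best[1]:
            best = (r, d)
    return best


def brute_force_within(ann, chrom, pos, cutoff, biotype=None, end=None):
    q_end = pos if end is None else end
    out = []
    for r in ann.records(biotype):
        if r.chrom != chrom:
            continue
        d = max(r.start - q_end, pos - r.end, 0)
        if d <= cutoff:
            out.append((r.gene_id, d))
    return sorted(out)
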