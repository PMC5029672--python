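"""Shared loader for the analysis scripts: the synthetic study written by
01_simulate.py, read back from results/data/."""

from pathlib import Path
import json

import pandas as pd

from lncscape.annotation import read_annotation
from lncscape.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
#: bulky simulated inputs and per-gene matrices live under scratch/ (regenerable
#: by re-running the scripts); results/ holds the compact summary tables
DATA = ROOT / "scratch" / "data"
BULK = ROOT / "scratch" / "derived"
RESULTS = ROOT / "results"

#: the synthetic study: three matched groups of 18, 2,000 genes (30% lncRNA),
#: 10% planted DE at log2FC 2, 10 cis pairs, PC- and MC-linked modules of 100,
#: 20 promoter-mark links at 8-fold, a 20+20 signature block, 9/74 SNPs
STUDY = SimulationConfig(
    seed=1,
    n_per_group=18,
    n_mrna=1400,
    n_lnc=600,
    frac_de=0.1,
    de_log2fc=2.0,
    nb_dispersion=0.1,
    n_cis_pairs=10,
    n_chip_links=20,
    chip_fold=8.0,
    module_spec=[
        {"size": 100, "trait": "PC", "intra_correlation": 0.8},
        {"size": 100, "trait": "MC", "intra_correlation": 0.8},
    ],
    signature_spec={"n_signature_genes": 20, "n_correlated_lnc": 20, "target_r": 0.8},
    n_snp_near=9,
    n_snp_far=74,
)


def load():
    ann = read_annotation(DATA / "annotation.gtf")
    counts = pd.read_csv(DATA / "counts.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(DATA / "samples.tsv", sep="\t", index_col=0)
    truth = json.loads((DATA / "truth.json").read_text())
    return ann, counts, samples, truth


def load_chip():
    tumor = pd.read_csv(DATA / "chip_tumor.tsv", sep="\t")
    normal = pd.read_csv(DATA / "chip_normal.tsv", sep="\t")
    return tumor, normal


def load_de_tables():
    return {
        comp: pd.read_csv(BULK / f"de_{comp}.tsv", sep="\t", index_col=0)
        for comp in ("PC-NC", "PC-MC", "MC-NC")
    }
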