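"""Generate the synthetic three-group study with planted truth.

Writes the full input bundle (annotation, counts, metadata, ChIP windows,
SNPs, truth) under scratch/data/ so the downstream analysis scripts can run
against a fixed, inspectable dataset.
"""

from lncscape.annotation import write_annotation
from lncscape.simulate import generate_all

from _data import DATA, STUDY


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    ann, counts, samples, truth, chip_t, chip_n, snps = generate_all(STUDY)
    write_annotation(ann, DATA / "annotation.gtf")
    write_annotation(ann, DATA / "annotation.bed")
    counts.to_csv(DATA / "counts.tsv", sep="\t")
    samples.to_csv(DATA / "samples.tsv", sep="\t")
    chip_t.to_csv(DATA / "chip_tumor.tsv", sep="\t", index=False)
    chip_n.to_csv(DATA / "chip_normal.tsv", sep="\t", index=False)
    snps.to_csv(DATA / "snps.tsv", sep="\t", index=False)
    truth.to_json(DATA / "truth.json")

    n_lnc = sum(r.biotype == "lncRNA" for r in ann)
    print(f"wrote {len(ann)} genes ({n_lnc} lncRNA) across {len(ann.chroms)} chromosomes")
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples "
          f"({STUDY.n_per_group}/group)")
    print(f"planted: DE per comparison "
          f"{ {c: len(g) for c, g in truth.de_genes.items()} }, "
          f"{len(truth.cis_pairs)} cis pairs, "
          f"{len(set(l['lnc'] for l in truth.chip_links))} promoter-linked lncRNAs, "
          f"{len(truth.signature_lnc)} signature lncRNAs, "
          f"{len(truth.snp_near)}/{len(snps)} near SNPs")


if __name__ == "__main__":
    main()
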