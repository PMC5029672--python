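"""Synthetic three-group RNA-seq / ChIP-seq / SNP data with planted truth.

The generator emulates the study design the pipeline targets: three matched
tissue groups (normal colon NC, primary tumor PC, liver metastasis MC) of
``n_per_group`` samples each, negative-binomial gene counts with lncRNAs
systematically lower-expressed than mRNAs, and planted structure for every
downstream stage — differential genes, cis lncRNA–mRNA neighbor pairs,
trait-linked co-expression modules, promoter H3K4me3 gains/losses concordant
with lncRNA regulation, signature-correlated lncRNAs, and SNPs near/far from
lncRNA loci.  Every planting is recorded in a :class:`Truth` object so each
stage's output can be scored against ground truth.

Counts are NB(mean mu_g * s_j, common dispersion) with library-size factors
s_j drawn log-uniform in [0.7, 1.3].  Matched-patient correlation is not
simulated by default; ``patient_effect_sd`` > 0 adds a shared per-patient
log-normal effect across the three groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneRecord, GenomeAnnotation

GROUPS = ("NC", "PC", "MC")
COMPARISONS = ("PC-NC", "PC-MC", "MC-NC")

#: genomic layout constants (bp)
CIS_PAIR_GAP = 500
CIS_ISOLATION_GAP = 5_000
SNP_NEAR_CUTOFF = 10_000


class SizingError(ValueError):
    """Genome too small to place the requested features."""


@dataclass
class ModuleSpec:
    """One planted co-expression module: ``trait`` is a group name or None."""

    size: int
    trait: str | None
    intra_correlation: float = 0.8
    #: share of the latent factor's variance carried by the group contrast;
    #: kept moderate so differently trait-linked modules stay near-orthogonal
    trait_strength: float = 0.35


@dataclass
class SignatureSpec:
    """Planted prognosis-signature block: mRNA signature genes plus lncRNAs
    sharing their latent factor at ``target_r``."""

    n_signature_genes: int = 20
    n_correlated_lnc: int = 20
    target_r: float = 0.8


@dataclass
class SimulationConfig:
    """All generator knobs.  Defaults mirror the emulated study design:
    18 samples per group, ~10% planted DE at log2FC 2, NB dispersion 0.1,
    lncRNA mean expression scaled down 4-fold relative to mRNA."""

    seed: int = 0
    n_per_group: int = 18
    n_mrna: int = 1400
    n_lnc: int = 600
    genome_size: int = 60_000_000
    n_chrom: int = 2
    nb_dispersion: float = 0.1
    lnc_expression_scale: float = 0.25
    de_log2fc: float = 2.0
    frac_de: float = 0.1
    n_cis_pairs: int = 10
    module_spec: list[ModuleSpec] = field(default_factory=list)
    n_chip_links: int = 20
    chip_fold: float = 8.0
    chip_window: int = 200
    chip_background_mean: float = 10.0
    chip_tss_enrich: float = 4.0
    n_snp_near: int = 9
    n_snp_far: int = 74
    signature_spec: SignatureSpec | None = None
    base_mean_log_mu: float = 4.7   # ln-scale location of mRNA base means (~110 counts)
    base_mean_log_sd: float = 1.0
    min_base_mean: float = 8.0
    patient_effect_sd: float = 0.0

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0 < self.lnc_expression_scale <= 1):
            raise ValueError("lnc_expression_scale must be in (0, 1]")
        if not (0 <= self.frac_de <= 1):
            raise ValueError("frac_de must be in [0, 1]")
        if self.frac_de > 0 and self.de_log2fc < 1:
            raise ValueError("de_log2fc must be >= 1 so planted genes clear the FC >= 2 call")
        if self.n_chip_links > 0 and self.chip_fold <= 4:
            raise ValueError("chip_fold must exceed 4, the differential-window call threshold")
        if self.chip_window <= 0:
            raise ValueError("chip_window must be positive")
        for k in ("n_per_group", "n_mrna", "n_lnc", "n_cis_pairs",
                  "n_chip_links", "n_snp_near", "n_snp_far"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be non-negative")
        self.module_spec = [
            ModuleSpec(**m) if isinstance(m, dict) else m for m in self.module_spec
        ]
        if isinstance(self.signature_spec, dict):
            self.signature_spec = SignatureSpec(**self.signature_spec)


@dataclass
class Truth:
    """Ground truth of all planted structure, keyed by generated gene ids."""

    de_genes: dict[str, dict[str, str]] = field(default_factory=dict)  # comp -> gene -> up/down
    de_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)  # true group-mean log2FC
    cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    module_labels: dict[str, int] = field(default_factory=dict)
    module_traits: dict[int, str | None] = field(default_factory=dict)
    chip_links: list[dict] = field(default_factory=list)  # {window:(chrom,start,end), lnc, direction}
    snp_near: set[str] = field(default_factory=set)
    signature_genes: list[str] = field(default_factory=list)
    signature_lnc: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["snp_near"] = sorted(self.snp_near)
        d["signature_lnc"] = sorted(self.signature_lnc)
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), stream]))


# -- annotation ------------------------------------------------------------


def generate_annotation(cfg: SimulationConfig) -> GenomeAnnotation:
    """Place ``n_mrna + n_lnc`` non-overlapping single-exon genes on
    ``n_chrom`` chromosomes.

    The first ``n_cis_pairs`` lncRNAs are laid out as isolated blocks
    (partner mRNA, 500 bp gap, lncRNA) with >= 5 kb of clearance on both
    sides, so the partner is each lncRNA's unambiguous nearest coding gene.
    """
    rng = _rng(cfg, 0)
    n_genes = cfg.n_mrna + cfg.n_lnc
    if cfg.n_cis_pairs > min(cfg.n_mrna, cfg.n_lnc):
        raise ValueError("n_cis_pairs exceeds available genes of one biotype")

    mrna_len = np.maximum(rng.lognormal(np.log(2000), 0.4, cfg.n_mrna).astype(int), 200)
    lnc_len = np.maximum(rng.lognormal(np.log(1000), 0.4, cfg.n_lnc).astype(int), 200)

    # interleave remaining genes in random order after the cis blocks
    free_ids = [("coding", i) for i in range(cfg.n_cis_pairs, cfg.n_mrna)] + [
        ("lncRNA", i) for i in range(cfg.n_cis_pairs, cfg.n_lnc)
    ]
    rng.shuffle(free_ids)

    per_chrom = cfg.genome_size // cfg.n_chrom
    records: list[GeneRecord] = []
    chrom_cursor = {f"chr{c + 1}": 10_000 for c in range(cfg.n_chrom)}
    chrom_names = list(chrom_cursor)

    def place(chrom: str, length: int, gap: int) -> tuple[int, int]:
        start = chrom_cursor[chrom] + gap
        end = start + length
        # keep a 10 kb + desert margin at the chromosome end for far SNPs
        if end > per_chrom - (SNP_NEAR_CUTOFF + 50_000):
            raise SizingError(
                f"genome_size {cfg.genome_size} too small to place all genes "
                f"(failed on {chrom} at {start})"
            )
        chrom_cursor[chrom] = end
        return start, end

    strand = lambda: "+" if rng.random() < 0.5 else "-"

    # cis blocks first, spread across chromosomes
    for k in range(cfg.n_cis_pairs):
        chrom = chrom_names[k % cfg.n_chrom]
        ms, me = place(chrom, int(mrna_len[k]), CIS_ISOLATION_GAP)
        records.append(GeneRecord(f"MRNA{k:05d}", "coding", chrom, ms, me, strand()))
        ls, le = place(chrom, int(lnc_len[k]), CIS_PAIR_GAP)
        records.append(GeneRecord(f"LNC{k:05d}", "lncRNA", chrom, ls, le, strand()))
        chrom_cursor[chrom] += CIS_ISOLATION_GAP  # clearance on the far side

    for j, (bt, i) in enumerate(free_ids):
        chrom = chrom_names[(cfg.n_cis_pairs + j) % cfg.n_chrom]
        gap = int(rng.integers(2_000, 10_000))
        length = int(mrna_len[i] if bt == "coding" else lnc_len[i])
        s, e = place(chrom, length, gap)
        prefix = "MRNA" if bt == "coding" else "LNC"
        records.append(GeneRecord(f"{prefix}{i:05d}", bt, chrom, s, e, strand()))

    return GenomeAnnotation(records)


# -- counts ----------------------------------------------------------------


def sample_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: sample_id, group, patient_id (patients matched across groups)."""
    rows = [
        (f"{g}{p + 1:02d}", g, f"P{p + 1:02d}")
        for g in GROUPS
        for p in range(cfg.n_per_group)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "patient_id"]).set_index("sample_id")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB with var = mu + dispersion * mu^2, via gamma-Poisson mixture
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) / shape)
    return rng.poisson(lam)


def _latent_loading(cfg: SimulationConfig, base_mean: np.ndarray, target_r: float) -> np.ndarray:
    """log2-scale loading on a unit-variance latent factor so that two member
    genes correlate at ~target_r on the log scale, given NB sampling noise."""
    var_noise = (1.0 / np.maximum(base_mean, 1e-6) + cfg.nb_dispersion) / (np.log(2) ** 2)
    return np.sqrt(target_r / (1.0 - target_r) * var_noise)


def generate_counts(
    cfg: SimulationConfig, ann: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame, Truth]:
    """Simulate the count matrix.

    Returns ``(counts, samples, truth)``: genes x samples integer counts,
    the sample table, and the planted truth.  Planted DE genes get a
    per-group multiplier of ``2**de_log2fc``; truth direction per pairwise
    comparison is derived from the exact group means, so every truth entry
    reflects what the generator actually did.
    """
    rng = _rng(cfg, 1)
    samples = sample_table(cfg)
    genes = ann.gene_ids
    is_lnc = np.array([ann[g].biotype == "lncRNA" for g in genes])
    n_genes, n_samp = len(genes), len(samples)
    truth = Truth()

    base = np.exp(rng.normal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, n_genes))
    base = np.maximum(base, cfg.min_base_mean)
    base[is_lnc] *= cfg.lnc_expression_scale

    group_of = samples["group"].to_numpy()
    group_mask = {g: group_of == g for g in GROUPS}

    # log2-scale offsets per gene per sample
    log2_offset = np.zeros((n_genes, n_samp))

    # ---- planted DE: each DE gene is up or down in exactly one tumor group
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_de = int(round(cfg.frac_de * n_genes))
    de_set = set(rng.choice(n_genes, size=n_de, replace=False).tolist()) if n_de else set()
    # cis-pair genes must be DE so the cis scan has signal: force-include them
    cis_gene_idx = [
        gene_pos[g]
        for k in range(cfg.n_cis_pairs)
        for g in (f"LNC{k:05d}", f"MRNA{k:05d}")
    ]
    de_set |= set(cis_gene_idx)
    de_idx = np.array(sorted(de_set), dtype=int)
    for gi in de_idx:
        grp = GROUPS[1 + int(rng.integers(0, 2))]  # PC or MC
        sign = 1.0 if rng.random() < 0.5 else -1.0
        log2_offset[gi, group_mask[grp]] += sign * cfg.de_log2fc
    # cis partners share direction and group so both members co-regulate
    for k in range(cfg.n_cis_pairs):
        li, mi = gene_pos[f"LNC{k:05d}"], gene_pos[f"MRNA{k:05d}"]
        log2_offset[mi] = log2_offset[li].copy()
        truth.cis_pairs.append((f"LNC{k:05d}", f"MRNA{k:05d}"))

    # ---- planted modules: shared latent factor per module
    module_pool = [i for i in range(n_genes) if i not in de_set]
    rng.shuffle(module_pool)
    cursor = 0
    for mid, ms in enumerate(cfg.module_spec, start=1):
        members = module_pool[cursor : cursor + ms.size]
        if len(members) < ms.size:
            raise ValueError("not enough non-DE genes to host module_spec")
        cursor += ms.size
        z = rng.normal(0, 1, n_samp)
        z = (z - z.mean()) / z.std()
        if ms.trait is not None:
            contrast = np.where(group_mask[ms.trait], 1.0, -0.5).astype(float)
            contrast = (contrast - contrast.mean()) / contrast.std()
            lam = ms.trait_strength
            f = np.sqrt(lam) * contrast + np.sqrt(1 - lam) * z
        else:
            f = z
        f = (f - f.mean()) / f.std()
        for gi in members:
            a = _latent_loading(cfg, base[gi : gi + 1], ms.intra_correlation)[0]
            sign = 1.0  # module members load with common sign (coherent module)
            log2_offset[gi] += sign * a * f
            truth.module_labels[genes[gi]] = mid
        truth.module_traits[mid] = ms.trait

    # ---- planted signature block: mRNA signature genes + correlated lncRNAs
    if cfg.signature_spec is not None:
        ss = cfg.signature_spec
        mrna_left = [i for i in module_pool[cursor:] if not is_lnc[i]]
        lnc_left = [i for i in module_pool[cursor:] if is_lnc[i]]
        if len(mrna_left) < ss.n_signature_genes or len(lnc_left) < ss.n_correlated_lnc:
            raise ValueError("not enough free genes to host signature_spec")
        sig_m = mrna_left[: ss.n_signature_genes]
        sig_l = lnc_left[: ss.n_correlated_lnc]
        f = rng.normal(0, 1, n_samp)
        f = (f - f.mean()) / f.std()
        for gi in sig_m + sig_l:
            a = _latent_loading(cfg, base[gi : gi + 1], ss.target_r)[0]
            log2_offset[gi] += a * f
        truth.signature_genes = [genes[i] for i in sig_m]
        truth.signature_lnc = {genes[i] for i in sig_l}

    # ---- library size factors and optional matched-patient effect
    size_factors = np.exp(rng.uniform(np.log(0.7), np.log(1.3), n_samp))
    if cfg.patient_effect_sd > 0:
        pat = samples["patient_id"].to_numpy()
        eff = {p: rng.normal(0, cfg.patient_effect_sd) for p in np.unique(pat)}
        log2_offset += np.array([eff[p] for p in pat])[None, :]

    mean = base[:, None] * (2.0 ** log2_offset) * size_factors[None, :]
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)

    # ---- truth DE sets from exact group means (library-size free)
    true_mean = base[:, None] * (2.0 ** log2_offset)
    gm = {g: true_mean[:, group_mask[g]].mean(axis=1) for g in GROUPS}
    for comp in COMPARISONS:
        a, b = comp.split("-")
        lfc = np.log2(gm[a] / gm[b])
        entry, entry_fc = {}, {}
        for gi in np.flatnonzero(np.abs(lfc) >= 1.0):
            entry[genes[gi]] = "up" if lfc[gi] > 0 else "down"
            entry_fc[genes[gi]] = round(float(lfc[gi]), 4)
        truth.de_genes[comp] = entry
        truth.de_log2fc[comp] = entry_fc

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples.index)
    return counts_df, samples, truth


# -- ChIP ------------------------------------------------------------------


def _window_grid(ann: GenomeAnnotation, cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for chrom in ann.chroms:
        last = max(r.end for r in ann.records() if r.chrom == chrom) + SNP_NEAR_CUTOFF
        n_win = int(np.ceil(last / cfg.chip_window))
        starts = np.arange(n_win) * cfg.chip_window
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + cfg.chip_window}))
    return pd.concat(rows, ignore_index=True)


def generate_chip(
    cfg: SimulationConfig, ann: GenomeAnnotation, truth: Truth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate tumor and normal H3K4me3 window counts on a shared grid.

    Background is Poisson(``chip_background_mean``); windows within 1 kb of
    any gene TSS get a ``chip_tss_enrich``-fold elevated baseline in both
    conditions (so the TSS aggregate profile is enriched).  For
    ``n_chip_links`` lncRNAs that are DE in PC-NC, the TSS windows instead
    get background * ``chip_fold`` in the concordant condition (tumor for
    up-regulated lncRNAs, normal for down-regulated), planting recoverable
    gained/lost promoter regions.  Updates ``truth.chip_links``.
    """
    rng = _rng(cfg, 2)
    grid = _window_grid(ann, cfg)
    n = len(grid)
    mu_t = np.full(n, cfg.chip_background_mean)
    mu_n = np.full(n, cfg.chip_background_mean)

    by_chrom = {c: grid.index[grid["chrom"] == c].to_numpy() for c in ann.chroms}
    starts = grid["start"].to_numpy()

    def tss_windows(chrom: str, pos: int, flank: int) -> np.ndarray:
        idx = by_chrom[chrom]
        lo, hi = pos - flank, pos + flank
        s = starts[idx]
        return idx[(s + cfg.chip_window > lo) & (s < hi)]

    for r in ann.records():
        w = tss_windows(r.chrom, r.tss, 1000)
        mu_t[w] = np.maximum(mu_t[w], cfg.chip_background_mean * cfg.chip_tss_enrich)
        mu_n[w] = np.maximum(mu_n[w], cfg.chip_background_mean * cfg.chip_tss_enrich)

    # pick DE lncRNAs (PC-NC) to link; direction follows the planted DE sign.
    # restrict to strong effects (true |log2FC| at least midway between the
    # call threshold and the planted effect) so every link is recoverable
    de_pcnc = truth.de_genes.get("PC-NC", {})
    strong = (1.0 + cfg.de_log2fc) / 2.0
    lfc_pcnc = truth.de_log2fc.get("PC-NC", {})
    de_lnc = sorted(
        g for g in de_pcnc
        if ann[g].biotype == "lncRNA" and abs(lfc_pcnc.get(g, 0.0)) >= strong
    )
    if cfg.n_chip_links > len(de_lnc):
        raise ValueError(
            f"n_chip_links={cfg.n_chip_links} exceeds the {len(de_lnc)} DE lncRNAs available"
        )
    chosen = list(rng.choice(de_lnc, size=cfg.n_chip_links, replace=False))
    truth.chip_links = []
    for g in chosen:
        rec = ann[g]
        direction = de_pcnc[g]
        w = tss_windows(rec.chrom, rec.tss, 400)
        level = cfg.chip_background_mean * cfg.chip_fold
        if direction == "up":
            mu_t[w] = level
            mu_n[w] = cfg.chip_background_mean
        else:
            mu_n[w] = level
            mu_t[w] = cfg.chip_background_mean
        for wi in w:
            truth.chip_links.append(
                {
                    "window": (grid.at[wi, "chrom"], int(grid.at[wi, "start"]), int(grid.at[wi, "end"])),
                    "lnc": g,
                    "direction": "gain" if direction == "up" else "loss",
                }
            )

    tumor = grid.copy()
    normal = grid.copy()
    tumor["count"] = rng.poisson(mu_t)
    normal["count"] = rng.poisson(mu_n)
    return tumor, normal


# -- SNPs ------------------------------------------------------------------


def generate_snps(cfg: SimulationConfig, ann: GenomeAnnotation, truth: Truth) -> pd.DataFrame:
    """Place ``n_snp_near`` SNPs within 10 kb of lncRNA loci (some inside)
    and ``n_snp_far`` farther than 10 kb from every lncRNA.

    Far SNPs go into the gene-free desert beyond the last gene of each
    chromosome; raises :class:`SizingError` when no valid far position
    exists.  Updates ``truth.snp_near``.
    """
    rng = _rng(cfg, 3)
    lncs = ann.records("lncRNA")
    if not lncs:
        raise ValueError("annotation contains no lncRNA loci")
    rows = []
    for i in range(cfg.n_snp_near):
        r = lncs[int(rng.integers(0, len(lncs)))]
        if rng.random() < 0.3:  # inside the locus
            pos = int(rng.integers(r.start, r.end))
        else:
            off = int(rng.integers(1, SNP_NEAR_CUTOFF + 1))
            pos = r.start - off if rng.random() < 0.5 else r.end + off - 1
            pos = max(pos, 0)
        sid = f"rsNEAR{i:04d}"
        rows.append((sid, r.chrom, pos))
        truth.snp_near.add(sid)

    # desert = beyond last gene + cutoff on each chromosome
    deserts = []
    per_chrom_last = {
        c: max(g.end for g in ann.records() if g.chrom == c) for c in ann.chroms
    }
    chrom_span = cfg.genome_size // cfg.n_chrom
    for c, last in per_chrom_last.items():
        lo, hi = last + SNP_NEAR_CUTOFF + 1, chrom_span - 1
        if hi > lo:
            deserts.append((c, lo, hi))
    if cfg.n_snp_far > 0 and not deserts:
        raise SizingError("no lncRNA-free region available for far SNPs")
    for i in range(cfg.n_snp_far):
        c, lo, hi = deserts[i % len(deserts)]
        pos = int(rng.integers(lo, hi))
        rows.append((f"rsFAR{i:04d}", c, pos))

    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    # sanity: planted far SNPs really are > cutoff from every lncRNA
    for _, s in snps[snps["snp_id"].str.startswith("rsFAR")].iterrows():
        hits = ann.genes_within(s["chrom"], int(s["pos"]), SNP_NEAR_CUTOFF, "lncRNA")
        if hits:
            raise SizingError("far-SNP placement collided with a lncRNA locus")
    return snps


def generate_all(cfg: SimulationConfig):
    """Run every generator stage; returns (ann, counts, samples, truth, chip_tumor, chip_normal, snps)."""
    ann = generate_annotation(cfg)
    counts, samples, truth = generate_counts(cfg, ann)
    chip_t, chip_n = generate_chip(cfg, ann, truth) if cfg.n_chip_links >= 0 else (None, None)
    snps = generate_snps(cfg, ann, truth)
    return ann, counts, samples, truth, chip_t, chip_n, snps
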