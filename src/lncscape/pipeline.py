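"""End-to-end orchestration: simulate (or load) inputs, then run
quantification, consensus DE, and the five downstream analyses, writing
every stage's tables plus a run manifest.

The config is a YAML mapping with either a ``simulate`` block (a
:class:`~lncscape.simulate.SimulationConfig`) or explicit input paths, plus
per-stage parameter overrides.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import chip as chip_mod
from . import cis as cis_mod
from . import de as de_mod
from . import expression as expr_mod
from . import network as net_mod
from . import signature as sig_mod
from . import snp as snp_mod
from .simulate import SimulationConfig, generate_all

logger = logging.getLogger(__name__)

STAGE_DEFAULTS = {
    "n_perm": 5000,
    "min_rpkm": cis_mod.DEFAULT_MIN_RPKM,
    "n_variable": None,
    "power": None,
    "min_module_size": net_mod.DEFAULT_MIN_MODULE_SIZE,
    "merge_cutoff": net_mod.DEFAULT_MERGE_CUTOFF,
    "promoter_flank": chip_mod.DEFAULT_PROMOTER_FLANK,
    "chip_fdr_cut": chip_mod.DEFAULT_FDR_CUT,
    "chip_fc_cut": chip_mod.DEFAULT_FC_CUT,
    "min_mean_r": sig_mod.DEFAULT_MIN_MEAN_R,
    "snp_cutoff": snp_mod.DEFAULT_CUTOFF,
    "expressed_threshold": 0.3,
    "signature_rows": "de",  # rows of the signature correlation matrix: "de" lncRNAs or "all"
    "active_threshold": 1.0,
}

_RANGES = {
    "chip_fdr_cut": (0.0, 1.0),
    "min_mean_r": (-1.0, 1.0),
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Return a list of violations; empty iff the config is runnable."""
    violations = []
    if "simulate" not in cfg and "counts" not in cfg:
        violations.append("config needs a 'simulate' block or a 'counts' input path")
    if "counts" in cfg:
        for key in ("counts", "samples", "annotation"):
            if key not in cfg:
                violations.append(f"missing input path: {key}")
            elif not Path(cfg[key]).exists():
                violations.append(f"{key}: path {cfg[key]} does not exist")
    params = cfg.get("params", {})
    for k, v in params.items():
        if k not in STAGE_DEFAULTS:
            violations.append(f"unknown parameter: {k}")
            continue
        if k in _RANGES and v is not None:
            lo, hi = _RANGES[k]
            if not (lo < v <= hi):
                violations.append(f"{k}={v} outside ({lo}, {hi}]")
        elif k in ("n_perm", "min_module_size", "promoter_flank", "snp_cutoff") and v is not None and v <= 0:
            violations.append(f"{k}={v} must be positive")
        elif k in ("min_rpkm", "expressed_threshold", "active_threshold", "chip_fc_cut") and v is not None and v < 0:
            violations.append(f"{k}={v} must be non-negative")
    if "simulate" in cfg:
        try:
            SimulationConfig(**cfg["simulate"])
        except (TypeError, ValueError) as exc:
            violations.append(f"simulate block invalid: {exc}")
    return violations


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute all stages in dependency order and write their outputs under
    ``outdir``; returns the manifest dict.  Any stage failure renames the
    output directory contents under ``failed/`` and re-raises with the stage
    name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    params = {**STAGE_DEFAULTS, **cfg.get("params", {})}
    manifest = {"config_hash": _config_hash(cfg), "stages": {}, "seed": seed}
    stage = "setup"
    try:
        t0 = time.time()
        if "simulate" in cfg:
            stage = "simulate"
            sim_kwargs = dict(cfg["simulate"])
            if seed is not None:
                sim_kwargs["seed"] = seed
            sim = SimulationConfig(**sim_kwargs)
            ann, counts, samples, truth, chip_t, chip_n, snps = generate_all(sim)
            ann_mod.write_annotation(ann, outdir / "annotation.gtf")
            ann_mod.write_annotation(ann, outdir / "annotation.bed")
            _write_tsv(counts, outdir / "counts.tsv")
            _write_tsv(samples, outdir / "samples.tsv")
            _write_tsv(chip_t, outdir / "chip_tumor.tsv", index=False)
            _write_tsv(chip_n, outdir / "chip_normal.tsv", index=False)
            _write_tsv(snps, outdir / "snps.tsv", index=False)
            truth.to_json(outdir / "truth.json")
        else:
            stage = "load"
            ann = ann_mod.read_annotation(cfg["annotation"])
            counts = pd.read_csv(cfg["counts"], sep="\t", index_col=0)
            samples = pd.read_csv(cfg["samples"], sep="\t", index_col=0)
            chip_t = pd.read_csv(cfg["chip_tumor"], sep="\t") if "chip_tumor" in cfg else None
            chip_n = pd.read_csv(cfg["chip_normal"], sep="\t") if "chip_normal" in cfg else None
            snps = pd.read_csv(cfg["snps"], sep="\t") if "snps" in cfg else None
        logger.info("stage inputs done in %.2fs", time.time() - t0)
        manifest["stages"]["inputs"] = {"genes": len(ann), "samples": len(samples)}

        stage = "quantify"
        t0 = time.time()
        expr = expr_mod.rpkm(counts, ann)
        _write_tsv(expr, outdir / "rpkm.tsv")
        detectable = expr_mod.expressed_set(expr, params["expressed_threshold"])
        active = expr_mod.expressed_set(expr, params["active_threshold"], strict=True)
        w, p_bio = expr_mod.biotype_expression_test(expr, ann)
        scores, evr = expr_mod.pca_scores(expr)
        _write_tsv(scores, outdir / "pca_scores.tsv")
        manifest["stages"]["quantify"] = {
            "detectable": len(detectable), "active": len(active),
            "biotype_wilcoxon_p": float(p_bio)}

        stage = "de"
        t0 = time.time()
        de_seed = seed if seed is not None else cfg.get("seed", 0)
        de_tables = de_mod.de_all_comparisons(counts, samples, n_perm=params["n_perm"], seed=de_seed)
        for comp, tab in de_tables.items():
            out = tab.copy()
            out.insert(0, "biotype", [ann[g].biotype for g in out.index])
            _write_tsv(out, outdir / f"de_{comp}.tsv")
        manifest["stages"]["de"] = {
            comp: int(tab["significant"].sum()) for comp, tab in de_tables.items()
        }

        stage = "cis"
        t0 = time.time()
        pairs = cis_mod.scan_cis_pairs(de_tables, ann, expr, samples, min_rpkm=params["min_rpkm"])
        _write_tsv(cis_mod.pairs_table(pairs), outdir / "cis_pairs.tsv", index=False)
        manifest["stages"]["cis"] = {
            "pairs": len(pairs), "coregulated": sum(p.coregulated for p in pairs)}

        stage = "modules"
        t0 = time.time()
        log_expr = expr_mod.log_rpkm(expr)
        mods = net_mod.build_network(
            log_expr, samples,
            n_variable=params["n_variable"], power=params["power"],
            min_module_size=params["min_module_size"], merge_cutoff=params["merge_cutoff"],
        )
        _write_tsv(mods.labels.rename("module").to_frame(), outdir / "module_labels.tsv")
        _write_tsv(mods.eigengenes, outdir / "module_eigengenes.tsv")
        _write_tsv(mods.trait_correlation, outdir / "module_trait_cor.tsv")
        manifest["stages"]["modules"] = {
            "n_modules": len(mods.module_ids), "power": mods.power}

        if chip_t is not None and chip_n is not None:
            stage = "chip"
            t0 = time.time()
            lnc_tss = [(r.chrom, r.tss, r.strand) for r in ann.records("lncRNA")]
            profile = chip_mod.tss_profile(chip_t, lnc_tss)
            np.savetxt(outdir / "tss_profile.tsv", profile, fmt="%.6g")
            regions = chip_mod.differential_windows(
                chip_t, chip_n, fdr_cut=params["chip_fdr_cut"], fc_cut=params["chip_fc_cut"]
            )
            _write_tsv(chip_mod.regions_table(regions), outdir / "chip_regions.tsv", index=False)
            links = chip_mod.link_regions(
                regions, de_tables["PC-NC"], ann, promoter_flank=params["promoter_flank"]
            )
            _write_tsv(chip_mod.links_table(links), outdir / "chip_links.tsv", index=False)
            chip_info = {"regions": len(regions), "links": len(links)}
            if len(links) >= 3:
                r, p = chip_mod.direction_consistency(links)
                chip_info |= {"consistency_r": round(r, 4), "consistency_p": float(p)}
            manifest["stages"]["chip"] = chip_info

        stage = "signature"
        t0 = time.time()
        sig_lists = {}
        for name, path in cfg.get("signature_lists", {}).items():
            sig_lists[name] = sig_mod.read_gene_list(path)
        if not sig_lists and "simulate" in cfg and truth.signature_genes:
            sig_lists = {"planted": set(truth.signature_genes)}
        if sig_lists:
            sig = sig_mod.merge_signatures(sig_lists, measured=set(expr.index))
            if params["signature_rows"] == "all":
                de_lnc_ids = sorted(g.gene_id for g in ann.records("lncRNA"))
            else:
                de_lnc_ids = sorted(
                    g for g in de_mod.significant_set(de_tables["PC-NC"])
                    if ann[g].biotype == "lncRNA"
                )
            if len(de_lnc_ids) >= 2 and sig.merged:
                cm = sig_mod.correlation_matrix(expr, de_lnc_ids, sorted(sig.merged))
                cm = sig_mod.cluster_matrix(cm)
                pos = sig_mod.extract_positive_set(cm, min_mean_r=params["min_mean_r"])
                _write_tsv(cm.matrix, outdir / "signature_correlation.tsv")
                (outdir / "signature_positive_set.txt").write_text("\n".join(sorted(pos)) + "\n")
                manifest["stages"]["signature"] = {
                    "signature_genes": len(sig.merged), "positive_lnc": len(pos)}

        if snps is not None:
            stage = "snps"
            t0 = time.time()
            table, summary = snp_mod.map_snps(snps, ann, de=de_tables["PC-NC"], cutoff=params["snp_cutoff"])
            _write_tsv(table, outdir / "snp_mapping.tsv", index=False)
            manifest["stages"]["snps"] = {
                "n_snps": summary.n_snps, "n_within": summary.n_within,
                "fraction_within": round(summary.fraction_within, 4),
                "n_within_de": summary.n_within_de,
            }

        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as exc:
        (outdir / "failed").mkdir(exist_ok=True)
        (outdir / "failed" / "stage.txt").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
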