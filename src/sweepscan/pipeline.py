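"""End-to-end pipeline: simulate/load -> scans -> windows -> annotate -> enrich.

Configuration is a flat-ish YAML mapping with one section per stage;
unknown keys are rejected before anything runs. Every run writes a
manifest (parameters, seed, package version, input checksums) next to its
outputs; reruns with the same config and inputs are byte-identical because
all stochastic stages are seed-driven.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .datatypes import SiteTestRecord, SnpScore, WindowRecord
from .io import (
    read_genes,
    read_phased_vcf,
    read_popmap,
    write_phased_vcf,
    write_popmap,
    write_table,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "focal",
    "vcf",
    "popmap",
    "genes",
    "simulate",
    "xpehh",
    "xpclr",
    "windows",
    "enrich",
}
_SIM_KEYS = {"N", "T", "s", "sweep_pos", "L", "M", "r_bp"}
_XPEHH_KEYS = {"cutoff", "max_gap", "enabled"}
_XPCLR_KEYS = {"grid_spacing", "window_radius", "r_bp", "N", "n_quad", "enabled"}
_WINDOW_KEYS = {"window_size", "alpha", "top_frac"}
_ENRICH_KEYS = {
    "matrix",
    "mode",
    "alpha",
    "scope",
    "n_sites",
    "n_hap",
    "enriched_sites",
    "k_categories",
}


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys anywhere in the config; fill defaults."""
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    for section, allowed in [
        ("simulate", _SIM_KEYS),
        ("xpehh", _XPEHH_KEYS),
        ("xpclr", _XPCLR_KEYS),
        ("windows", _WINDOW_KEYS),
        ("enrich", _ENRICH_KEYS),
    ]:
        sub = cfg.get(section) or {}
        bad = set(sub) - allowed
        if bad:
            raise ValueError(
                f"unknown key(s) in '{section}': {', '.join(sorted(bad))}"
            )
    cfg.setdefault("seed", 0)
    cfg.setdefault("focal", "focal")
    if "simulate" not in cfg and ("vcf" not in cfg or "popmap" not in cfg):
        raise ValueError("config needs either a 'simulate' section or vcf+popmap")
    return cfg


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict, outdir: str | Path | None = None) -> Path:
    """Run all configured stages in dependency order; return the outdir."""
    cfg = validate_config(dict(cfg))
    out = Path(outdir or cfg.get("outdir", "sweepscan_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    focal = cfg["focal"]
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "inputs": {},
        "stages": [],
    }

    def stage(name):
        logger.info("[%s] running", name)
        manifest["stages"].append(name)

    try:
        if "simulate" in cfg:
            stage("simulate")
            from .simulate import SweepSimConfig, simulate_two_pop_sweep

            sim = dict(cfg["simulate"] or {})
            sim_cfg = SweepSimConfig(seed=seed, **sim)
            hm, truth = simulate_two_pop_sweep(sim_cfg)
            vcf_path = out / "simulated.vcf"
            names = write_phased_vcf(hm, vcf_path)
            labels = [str(hm.hap_pop[2 * i]) for i in range(len(names))]
            popmap_path = out / "popmap.tsv"
            write_popmap(names, labels, popmap_path)
            write_table([truth], out / "truth.tsv")
            focal = sim_cfg.focal_label
        else:
            vcf_path = Path(cfg["vcf"])
            popmap_path = Path(cfg["popmap"])

        manifest["inputs"]["vcf"] = _checksum(vcf_path)
        manifest["inputs"]["popmap"] = _checksum(popmap_path)

        stage("load")
        mats, exclusions = read_phased_vcf(vcf_path, read_popmap(popmap_path))
        manifest["excluded_sites"] = exclusions

        wincfg = cfg.get("windows") or {}
        window_size = int(wincfg.get("window_size", 25_000))
        alpha = float(wincfg.get("alpha", 0.01))
        top_frac = float(wincfg.get("top_frac", 0.01))

        all_hits = []
        genes = None
        if cfg.get("genes"):
            genes = read_genes(cfg["genes"])
            manifest["inputs"]["genes"] = _checksum(Path(cfg["genes"]))

        xpehh_cfg = cfg.get("xpehh") or {}
        if xpehh_cfg.get("enabled", True):
            stage("xpehh")
            from .windows import summarize
            from .xpehh import xpehh_scan

            scores = xpehh_scan(
                mats,
                focal=focal,
                cutoff=float(xpehh_cfg.get("cutoff", 0.05)),
                max_gap=int(xpehh_cfg.get("max_gap", 200_000)),
            )
            write_table(scores, out / "snp_scores.tsv", record_type=SnpScore)
            stage("windows_xpehh")
            ws, _ = summarize(
                [(s.chrom, s.pos, s.xpehh_z) for s in scores],
                mode="xpehh",
                window_size=window_size,
                alpha=alpha,
            )
            write_table(ws, out / "windows_xpehh.tsv", record_type=WindowRecord)
            if genes:
                from .annotate import overlap_genes

                all_hits += overlap_genes(ws, genes, method="xpehh")

        xpclr_cfg = cfg.get("xpclr") or {}
        if xpclr_cfg.get("enabled", True):
            stage("xpclr")
            from .windows import summarize
            from .xpclr import clr_scan, estimate_omega, frequency_table

            points = []
            for hm in mats:
                ft = frequency_table(hm, focal=focal)
                omega = estimate_omega(ft)
                manifest.setdefault("omega", {})[hm.chrom] = omega
                points += clr_scan(
                    ft,
                    omega,
                    grid_spacing=int(xpclr_cfg.get("grid_spacing", 2500)),
                    window_radius=int(xpclr_cfg.get("window_radius", 12_500)),
                    r_bp=float(xpclr_cfg.get("r_bp", 1e-8)),
                    N=float(xpclr_cfg.get("N", 500)),
                )
            write_table(points, out / "clr.tsv")
            stage("windows_xpclr")
            ws, threshold = summarize(
                [(p.chrom, p.pos, p.clr) for p in points],
                mode="xpclr",
                window_size=window_size,
                top_frac=top_frac,
            )
            manifest["xpclr_threshold"] = threshold
            write_table(ws, out / "windows_xpclr.tsv", record_type=WindowRecord)
            if genes:
                from .annotate import overlap_genes

                all_hits += overlap_genes(ws, genes, method="xpclr")

        if genes:
            stage("annotate")
            rows = [
                {
                    "gene_id": h.gene_id,
                    "comparison": h.comparison,
                    "method": h.method,
                    "n_windows": len(h.windows),
                }
                for h in all_hits
            ]
            import pandas as pd

            pd.DataFrame(
                rows, columns=["gene_id", "comparison", "method", "n_windows"]
            ).to_csv(out / "genes.tsv", sep="\t", index=False)

        encfg = cfg.get("enrich") or {}
        if encfg:
            stage("enrich")
            from .enrichment import bonferroni, enumerate_tests, read_site_matrix

            if "matrix" in encfg:
                matrix = read_site_matrix(encfg["matrix"])
                manifest["inputs"]["matrix"] = _checksum(Path(encfg["matrix"]))
            else:
                from .simulate import simulate_gene_sites

                matrix, _ = simulate_gene_sites(
                    n_sites=int(encfg.get("n_sites", 100)),
                    n_hap=int(encfg.get("n_hap", 20)),
                    enriched_sites=[
                        tuple(e) for e in encfg.get("enriched_sites", [])
                    ],
                    k_categories=int(encfg.get("k_categories", 2)),
                    seed=seed,
                )
                matrix.to_csv(out / "site_matrix.tsv", sep="\t")
            records = enumerate_tests(matrix, mode=encfg.get("mode", "indel"))
            bonferroni(
                records,
                alpha=float(encfg.get("alpha", 0.05)),
                scope=encfg.get("scope", "per_gene"),
            )
            write_table(records, out / "enrichment.tsv", record_type=SiteTestRecord)
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "config"
        raise RuntimeError(f"pipeline failed in stage '{failed}': {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
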