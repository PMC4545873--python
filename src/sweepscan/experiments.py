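"""Self-contained validation experiments on synthetic data.

Each function simulates data under known conditions, runs the relevant
part of the pipeline end to end, and returns summary statistics. They
back both the acceptance tests and the reproduction script, so the same
code path produces both.

The end-to-end haplotype experiment scans each sweep replicate against a
fixed panel of neutral background chromosomes simulated under identical
conditions. Rank-based empirical p-values smaller than 0.01 require more
than 100 ranked windows, so the background supplies the genome-scale
empirical distribution that a real whole-genome scan gets for free (the
windows of one 2.5-Mb chromosome alone cannot reach p < 0.01). The
background is simulated once and shared across replicates; each
replicate standardizes its scores jointly with the background and ranks
all windows together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import HaplotypeMatrix
from .simulate import SweepSimConfig, simulate_gene_sites, simulate_two_pop_sweep
from .windows import summarize
from .xpehh import standardize_scores, xpehh_scan

logger = logging.getLogger(__name__)

SWEEP_CONDITIONS = dict(N=500, T=200, s=0.1, L=2_500_000, M=2000, r_bp=1e-8,
                        sweep_pos=1_250_000)


@dataclass
class EndToEndResult:
    n_reps: int
    window_hits: int  # replicates whose sweep window is flagged significant
    z_hits: int  # replicates with mean z near the sweep above the genome mean
    sweep_window_ps: list[float] = field(default_factory=list)
    mean_z_at_sweep: list[float] = field(default_factory=list)
    n_windows: int = 0


def _seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit seeds from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def simulate_background(
    n_chroms: int, seed: int, conditions: dict | None = None
) -> list[HaplotypeMatrix]:
    """Neutral (s=0) chromosomes under the sweep study conditions."""
    conditions = dict(conditions or SWEEP_CONDITIONS)
    conditions["s"] = 0.0
    mats = []
    for i, s in enumerate(_seeds(seed, n_chroms)):
        hm, _ = simulate_two_pop_sweep(SweepSimConfig(seed=s, **conditions))
        hm.chrom = f"bg{i}"
        mats.append(hm)
    return mats


def end_to_end_xpehh_power(
    seed: int,
    n_reps: int = 20,
    n_background: int = 40,
    conditions: dict | None = None,
    near_radius: int = 12_500,
) -> EndToEndResult:
    """Sweep detection by the full XP-EHH -> windows -> empirical-p chain.

    For each replicate: simulate a hard sweep, scan it together with the
    shared neutral background, and check (a) whether the 25-kb window
    containing the sweep site is flagged at empirical p < 0.01 and (b)
    whether the mean standardized score within ``near_radius`` of the
    sweep site exceeds the genome-wide mean.
    """
    conditions = dict(conditions or SWEEP_CONDITIONS)
    bg = simulate_background(n_background, seed + 1)
    bg_scores = xpehh_scan(bg, standardize=False)
    logger.info("background: %d chromosomes, %d scored SNPs",
                n_background, len(bg_scores))

    result = EndToEndResult(n_reps=n_reps, window_hits=0, z_hits=0)
    for rep_seed in _seeds(seed, n_reps):
        cfg = SweepSimConfig(seed=rep_seed, **conditions)
        hm, truth = simulate_two_pop_sweep(cfg)
        rep_scores = xpehh_scan(hm, standardize=False)
        combined = rep_scores + bg_scores
        standardize_scores(combined)
        ws, _ = summarize(
            [(s.chrom, s.pos, s.xpehh_z) for s in combined], mode="xpehh"
        )
        result.n_windows = len(ws)
        sweep_w = next(
            (w for w in ws
             if w.chrom == hm.chrom and w.start <= truth.sweep_pos < w.end),
            None,
        )
        if sweep_w is not None:
            result.sweep_window_ps.append(sweep_w.empirical_p)
            result.window_hits += sweep_w.significant
        near = [s.xpehh_z for s in rep_scores
                if s.xpehh_z is not None
                and abs(s.pos - truth.sweep_pos) <= near_radius]
        allz = [s.xpehh_z for s in combined if s.xpehh_z is not None]
        if near:
            result.mean_z_at_sweep.append(float(np.mean(near)))
            result.z_hits += float(np.mean(near)) > float(np.mean(allz))
    return result


def xpclr_threshold_on_sweep_genome(seed: int, n_background: int = 8) -> dict:
    """Top-1% CLR threshold and sweep-window flagging on one synthetic
    genome (sweep chromosome + neutral background chromosomes)."""
    from .xpclr import clr_scan, estimate_omega, frequency_table

    conditions = dict(SWEEP_CONDITIONS)
    hm, truth = simulate_two_pop_sweep(SweepSimConfig(seed=seed, **conditions))
    mats = [hm] + simulate_background(n_background, seed + 1)
    points = []
    for m in mats:
        ft = frequency_table(m)
        points += clr_scan(ft, estimate_omega(ft), n_quad=256)
    ws, threshold = summarize(
        [(p.chrom, p.pos, p.clr) for p in points], mode="xpclr"
    )
    sweep_w = next(
        (w for w in ws
         if w.chrom == hm.chrom and w.start <= truth.sweep_pos < w.end),
        None,
    )
    return {
        "threshold": threshold,
        "n_windows": len(ws),
        "sweep_window_significant": bool(sweep_w and sweep_w.significant),
    }


def clr_sweep_recovery(
    seed: int,
    n_reps: int = 50,
    omega: float = 0.05,
    s: float = 0.05,
    n_sites: int = 500,
    n_focal: int = 50,
    L: int = 1_000_000,
) -> dict:
    """Localization of a known sweep from model-simulated frequencies.

    A hit = the argmax CLR grid point falls in the true sweep's 25-kb
    window or an adjacent one. The scan window radius is matched to the
    sweep's recombination footprint (1/(r_bp * t_s) is about 1.3 Mb at
    s=0.05), where the escape-probability gradient carries the position
    information.
    """
    from .xpclr import clr_scan, estimate_omega, simulate_frequencies

    sweep_pos = L // 2
    hits = 0
    for rep_seed in _seeds(seed, n_reps):
        rng = np.random.default_rng(rep_seed)
        ft = simulate_frequencies(
            n_sites, omega, n_focal=n_focal, L=L, rng=rng,
            sweep_pos=sweep_pos, s=s,
        )
        pts = clr_scan(
            ft, estimate_omega(ft),
            window_radius=100_000, grid_spacing=5000, n_quad=256,
        )
        best = max((p for p in pts if p.clr is not None), key=lambda p: p.clr)
        hits += abs(best.pos // 25_000 - sweep_pos // 25_000) <= 1
    return {"hits": hits, "n_reps": n_reps}


def omega_recovery(seed: int, omega: float = 0.05, n_sites: int = 5000) -> dict:
    """Drift-variance recovery from neutrally simulated frequencies."""
    from .xpclr import estimate_omega, simulate_frequencies

    rng = np.random.default_rng(seed)
    ft = simulate_frequencies(n_sites, omega, n_focal=1000, L=50_000_000, rng=rng)
    return {"omega_hat": estimate_omega(ft), "omega_true": omega, "n_sites": n_sites}


def enrichment_power(seed: int, n_reps: int = 20, odds: float = 50.0) -> dict:
    """Planted single-site enrichment attains the gene's minimum p."""
    from .enrichment import enumerate_tests

    wins = 0
    for rep_seed in _seeds(seed, n_reps):
        matrix, _ = simulate_gene_sites(
            n_sites=100, n_hap=20,
            enriched_sites=[(30, "Berkshire", "Y", odds)], seed=rep_seed,
        )
        records = enumerate_tests(matrix, mode="indel")
        min_p = min(r.p_raw for r in records)
        planted = next(
            r for r in records
            if (r.site, r.breed, r.category) == (31, "Berkshire", "Y")
        )
        wins += planted.p_raw == min_p
    return {"wins": wins, "n_reps": n_reps}


def fisher_null_calibration(seed: int, min_tests: int = 10_000) -> dict:
    """Type-I rate of the one-sided Fisher test under the odds=1 generator."""
    from .enrichment import enumerate_tests

    n_tests = 0
    n_hits = 0
    i = 0
    seeds = _seeds(seed, 64)
    while n_tests < min_tests:
        matrix, _ = simulate_gene_sites(n_sites=200, n_hap=20, seed=seeds[i])
        records = enumerate_tests(matrix, mode="indel")
        n_tests += len(records)
        n_hits += sum(r.p_raw <= 0.05 for r in records)
        i += 1
    return {"rate": n_hits / n_tests, "n_tests": n_tests}
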