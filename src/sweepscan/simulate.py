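"""Forward Wright-Fisher simulation of a two-population hard sweep, and a
categorical gene-site generator for the enrichment tests.

Two diploid populations of size N split from a common ancestral haplotype
pool and evolve T generations of Wright-Fisher reproduction with
per-meiosis recombination. The focal population carries additive selection
(fitness 1, 1+s, 1+2s) on a designated standing variant; the reference
population drifts neutrally. No new mutation arises after the split, so
both populations segregate subsets of the same ancestral site set -- the
situation a jointly called variant panel presents to the scan statistics.

If the selected allele is lost in the focal population the focal run is
restarted from the split with a fresh sub-stream (the reference population
uses its own stream and is never perturbed by restarts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import HaplotypeMatrix, SweepTruth

logger = logging.getLogger(__name__)

MAX_RESTARTS = 1000


@dataclass
class SweepSimConfig:
    """Parameters of one two-population sweep simulation.

    N is the diploid size of each population; T the generations since the
    split; s the additive selection coefficient on the swept allele in the
    focal population (0 gives a fully neutral run); L the chromosome length
    in bp; M the number of segregating sites in the ancestral pool; r_bp
    the per-bp per-generation recombination probability.
    """

    N: int = 500
    T: int = 200
    s: float = 0.1
    sweep_pos: int = 1_250_000
    L: int = 2_500_000
    M: int = 2000
    r_bp: float = 1e-8
    seed: int = 0
    hard_sweep: bool = True  # selected allele starts as a single ancestral copy
    focal_label: str = "focal"
    ref_label: str = "reference"

    def __post_init__(self) -> None:
        if self.N < 10:
            raise ValueError("N must be >= 10")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0 <= self.s <= 1:
            raise ValueError("s must lie in [0,1]")
        if not 0 <= self.sweep_pos < self.L:
            raise ValueError("sweep_pos must lie in [0, L)")
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.r_bp < 0:
            raise ValueError("r_bp must be >= 0")


def _ancestral_pool(cfg: SweepSimConfig, rng: np.random.Generator):
    """Build 2N ancestral haplotypes over M sites.

    Site positions are uniform on [0, L); one site is pinned to sweep_pos
    so the selected locus is itself genotyped. Derived-allele counts are
    drawn from the neutral SFS shape P(i) proportional to 1/i,
    i = 1..2N-1, and alleles are assigned to random haplotypes per site.
    Under hard-sweep conditioning the selected allele instead starts as a
    single copy, so the sweep drags one ancestral haplotype.
    """
    n_hap = 2 * cfg.N
    pos = rng.integers(0, cfg.L, size=cfg.M - 1)
    positions = np.unique(np.concatenate([pos, [cfg.sweep_pos]]))
    m = positions.size
    i = np.arange(1, n_hap)
    sfs = 1.0 / i
    sfs /= sfs.sum()
    counts = rng.choice(i, size=m, p=sfs)
    sweep_idx = int(np.searchsorted(positions, cfg.sweep_pos))
    if cfg.hard_sweep and cfg.s > 0:
        counts[sweep_idx] = 1
    alleles = np.zeros((n_hap, m), dtype=np.uint8)
    for j in range(m):
        carriers = rng.choice(n_hap, size=counts[j], replace=False)
        alleles[carriers, j] = 1
    return positions, alleles, sweep_idx


def _evolve(
    haps: np.ndarray,
    positions: np.ndarray,
    cfg: SweepSimConfig,
    rng: np.random.Generator,
    selected_site: int | None,
) -> np.ndarray | None:
    """Run T generations of diploid Wright-Fisher reproduction.

    Haplotype rows (2i, 2i+1) form diploid individual i. Each offspring
    draws two parents (fitness-weighted when selected_site is set) and one
    recombinant gamete from each. Returns None if the selected allele is
    lost (the caller restarts).
    """
    n_hap, m = haps.shape
    N = n_hap // 2
    mean_xo = cfg.r_bp * cfg.L
    for _ in range(cfg.T):
        if selected_site is not None:
            dosage = (
                haps[0::2, selected_site].astype(float)
                + haps[1::2, selected_site]
            )
            if dosage.sum() == 0:
                return None
            w = 1.0 + cfg.s * dosage
            p = w / w.sum()
            parents = rng.choice(N, size=n_hap, p=p)
        else:
            parents = rng.integers(0, N, size=n_hap)
        start_hap = rng.integers(0, 2, size=n_hap)
        n_xo = rng.poisson(mean_xo, size=n_hap)
        new = haps[2 * parents + start_hap].copy()
        for g in np.flatnonzero(n_xo):
            breaks = np.sort(rng.integers(0, cfg.L, size=n_xo[g]))
            cut = np.searchsorted(positions, breaks, side="right")
            h0 = haps[2 * parents[g] + start_hap[g]]
            h1 = haps[2 * parents[g] + 1 - start_hap[g]]
            gamete = h0.copy()
            use_other = False
            prev = 0
            for cpos in list(cut) + [m]:
                if use_other:
                    gamete[prev:cpos] = h1[prev:cpos]
                prev = cpos
                use_other = not use_other
            new[g] = gamete
        haps = new
    if selected_site is not None and haps[:, selected_site].sum() == 0:
        return None
    return haps


def simulate_two_pop_sweep(
    cfg: SweepSimConfig,
) -> tuple[HaplotypeMatrix, SweepTruth]:
    """Simulate the split, drift both populations, sweep the focal one.

    Returns the pooled final haplotypes (focal rows first) with monomorphic
    sites dropped, plus the ground truth (sweep position, s, final selected
    allele frequency per population, restart count).
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_pool, ss_ref, ss_focal = root.spawn(3)
    rng_pool = np.random.default_rng(ss_pool)
    positions, anc, sweep_idx = _ancestral_pool(cfg, rng_pool)

    ref = _evolve(anc.copy(), positions, cfg, np.random.default_rng(ss_ref), None)

    selected = sweep_idx if cfg.s > 0 else None
    restarts = 0
    focal_streams = ss_focal.spawn(MAX_RESTARTS + 1)
    while True:
        focal = _evolve(
            anc.copy(),
            positions,
            cfg,
            np.random.default_rng(focal_streams[restarts]),
            selected,
        )
        if focal is not None:
            break
        restarts += 1
        if restarts > MAX_RESTARTS:
            raise RuntimeError(
                f"sweep failed to establish after {MAX_RESTARTS} restarts "
                f"(s={cfg.s}, N={cfg.N}, T={cfg.T}); the selected allele "
                "was lost every time"
            )
    if restarts:
        logger.info("focal sweep restarted %d time(s)", restarts)

    pooled = np.vstack([focal, ref])
    labels = np.array(
        [cfg.focal_label] * focal.shape[0] + [cfg.ref_label] * ref.shape[0]
    )
    focal_freq = float(focal[:, sweep_idx].mean())
    ref_freq = float(ref[:, sweep_idx].mean())

    poly = (pooled.sum(axis=0) > 0) & (pooled.sum(axis=0) < pooled.shape[0])
    hm = HaplotypeMatrix(
        chrom="chr1",
        positions=positions[poly],
        alleles=pooled[:, poly],
        hap_pop=labels,
    )
    truth = SweepTruth(
        sweep_pos=cfg.sweep_pos,
        s=cfg.s,
        focal_final_freq=focal_freq,
        ref_final_freq=ref_freq,
        seed=cfg.seed,
        restarts=restarts,
    )
    return hm, truth


@dataclass
class GeneSiteTruth:
    """One planted enrichment: (site, breed, category, odds)."""

    site: int
    breed: str
    category: str
    odds: float


def simulate_gene_sites(
    n_sites: int,
    breeds: tuple[str, str, str] = ("Berkshire", "Landrace", "Yorkshire"),
    n_hap: int = 20,
    enriched_sites: list[tuple[int, str, str, float]] | None = None,
    k_categories: int = 2,
    seed: int = 0,
) -> tuple["pd.DataFrame", list[GeneSiteTruth]]:
    """Generate a per-haplotype categorical site matrix with planted skews.

    Null sites draw every haplotype's category from one shared per-site
    distribution, identical across breeds. With k_categories=2 the labels
    are "Y"/"N" (Indel presence coding) and the shared P(Y) is drawn from
    Beta(1, 4): a present Indel is a derived variant and derived-variant
    frequencies are skewed low in real panels. With k >= 3 (amino-acid
    residues, no canonical ancestral label) the shared distribution is
    Dirichlet(1,..,1). An enriched site multiplies the focal breed's odds
    of the focal category by the stated factor (odds > 1).

    Returns a DataFrame (index = haplotype ids, first column ``breed``,
    site columns ``site_1..site_n``, 1-based site labels) and the list of
    planted truths.
    """
    import pandas as pd

    if k_categories < 2:
        raise ValueError("k_categories must be >= 2")
    enriched_sites = enriched_sites or []
    if k_categories == 2:
        cats = np.array(["Y", "N"])
    else:
        cats = np.array([f"C{i}" for i in range(k_categories)])
    for site, breed, cat, odds in enriched_sites:
        if not 0 <= site < n_sites:
            raise ValueError(f"enriched site index {site} out of range")
        if breed not in breeds:
            raise ValueError(f"unknown breed {breed!r}")
        if cat not in cats:
            raise ValueError(f"unknown category {cat!r}")
        if odds <= 1:
            raise ValueError("enrichment odds must be > 1")
    enriched_by_site = {site: (b, c, o) for site, b, c, o in enriched_sites}

    rng = np.random.default_rng(seed)
    n_total = n_hap * len(breeds)
    breed_col = np.repeat(list(breeds), n_hap)
    matrix = np.empty((n_total, n_sites), dtype=object)
    base_alpha = np.array([1.0, 4.0]) if k_categories == 2 else np.ones(k_categories)
    for j in range(n_sites):
        base = rng.dirichlet(base_alpha)
        for bi, breed in enumerate(breeds):
            p = base.copy()
            if j in enriched_by_site and enriched_by_site[j][0] == breed:
                _, cat, odds = enriched_by_site[j]
                ci = int(np.flatnonzero(cats == cat)[0])
                # odds-multiplication on the focal category
                w = p.copy()
                w[ci] = 0
                denom = w.sum()
                if denom == 0 or np.isinf(odds):
                    p = np.zeros(k_categories)
                    p[ci] = 1.0
                else:
                    oddsval = odds * p[ci] / denom
                    p = w / denom * (1 / (1 + oddsval))
                    p[ci] = oddsval / (1 + oddsval)
            rows = slice(bi * n_hap, (bi + 1) * n_hap)
            matrix[rows, j] = rng.choice(cats, size=n_hap, p=p)

    df = pd.DataFrame(
        matrix,
        index=[f"hap{i}" for i in range(n_total)],
        columns=[f"site_{j + 1}" for j in range(n_sites)],
    )
    df.insert(0, "breed", breed_col)
    truth = [GeneSiteTruth(s, b, c, o) for s, b, c, o in enriched_sites]
    return df, truth
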