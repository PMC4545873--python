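"""Core data containers shared across the scan pipeline.

Coordinates are 0-based, half-open everywhere inside the package;
conversion from 1-based file formats (VCF, GFF3) happens at the file
boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 alleles for one chromosome.

    Rows are haplotypes (two per diploid sample), columns are sites in
    strictly increasing physical order. ``hap_pop`` labels each haplotype
    row with its population.
    """

    chrom: str
    positions: np.ndarray  # int64, strictly increasing, 0-based bp
    alleles: np.ndarray  # uint8 {0,1}, shape (n_haplotypes, n_sites)
    hap_pop: np.ndarray  # str labels, shape (n_haplotypes,)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.hap_pop = np.asarray(self.hap_pop)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError(
                f"alleles has {self.alleles.shape[1]} columns but "
                f"{self.positions.size} positions given"
            )
        if self.hap_pop.size != self.alleles.shape[0]:
            raise ValueError("hap_pop must label every haplotype row")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.alleles, (0, 1))
        if bad.any():
            raise ValueError("alleles must contain only 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def population_rows(self, label: str) -> np.ndarray:
        rows = np.flatnonzero(self.hap_pop == label)
        if rows.size == 0:
            raise ValueError(f"no haplotypes labelled {label!r}")
        return rows

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.hap_pop:
            if p not in seen:
                seen.append(str(p))
        return seen


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int
    gene_id: str
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass
class FrequencyTable:
    """Per-site derived-allele frequencies for the two-population CLR model.

    ``p_ref`` is the reference-population frequency; the focal population
    enters through its sampled derived-allele counts ``k_focal`` out of
    ``n_focal`` chromosomes.
    """

    chrom: str
    positions: np.ndarray
    p_ref: np.ndarray
    k_focal: np.ndarray
    n_focal: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.p_ref = np.asarray(self.p_ref, dtype=float)
        self.k_focal = np.asarray(self.k_focal, dtype=np.int64)
        self.n_focal = np.asarray(self.n_focal, dtype=np.int64)
        n = self.positions.size
        if not (self.p_ref.size == self.k_focal.size == self.n_focal.size == n):
            raise ValueError("all per-site arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any((self.p_ref < 0) | (self.p_ref > 1)):
            raise ValueError("p_ref must lie in [0,1]")
        if np.any((self.k_focal < 0) | (self.k_focal > self.n_focal)):
            raise ValueError("k_focal must lie in [0, n_focal]")

    @property
    def n_sites(self) -> int:
        return self.positions.size


@dataclass
class SnpScore:
    """Per-SNP XP-EHH result."""

    chrom: str
    pos: int
    ihh_focal: float
    ihh_ref: float
    xpehh_raw: float | None  # None when either iHH is 0
    xpehh_z: float | None = None
    edge_flag: bool = False


@dataclass
class ClrGridPoint:
    """One tested sweep position from the composite-likelihood scan."""

    chrom: str
    pos: int
    clr: float | None  # None when the window held no sites
    s_hat: float | None
    n_sites: int = 0


@dataclass
class WindowRecord:
    """One non-overlapping genomic window with its summary statistic."""

    chrom: str
    start: int
    end: int
    snp_count: int
    stat_max: float
    bin_id: int | None = None
    empirical_p: float | None = None
    significant: bool = False


@dataclass
class SiteTestRecord:
    """One (gene, site, breed, category) Fisher 2x2 enrichment test.

    a = focal breed & focal category, b = focal breed & other category,
    c = other breeds & focal category, d = other breeds & other category.
    """

    gene_id: str
    site: int
    breed: str
    category: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_raw: float
    p_bonf: float | None = None
    m_tests: int | None = None
    significant: bool = False


@dataclass
class SweepTruth:
    """Simulator ground truth for one two-population sweep replicate."""

    sweep_pos: int
    s: float
    focal_final_freq: float
    ref_final_freq: float
    seed: int
    restarts: int = 0


@dataclass
class GeneHit:
    """A gene overlapped by at least one significant window."""

    gene_id: str
    comparison: str
    method: str
    windows: list[tuple[int, int]] = field(default_factory=list)
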