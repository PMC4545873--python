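import numpy as np
import pytest

from sweepscan.datatypes import HaplotypeMatrix
from sweepscan.xpehh import ehh, ihh, standardize_scores, xpehh_scan

from conftest import random_haplotype_matrix


def ehh_pairwise_oracle(alleles, core, target):
    """Identical-pair fraction computed by explicit pairwise comparison.

    Independent of the grouping implementation: walks every haplotype pair
    and checks allele-by-allele identity over the inclusive span.
    """
    n = alleles.shape[0]
    lo, hi = min(core, target), max(core, target)
    same = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(alleles[i, lo : hi + 1], alleles[j, lo : hi + 1]):
                same += 1
    return 2 * same / (n * (n - 1))


def ihh_brute_force(hm_pop, hm_pooled, core, cutoff, max_gap):
    """Trapezoid integral of pairwise-oracle EHH, truncated by pooled EHH.

    Materializes every span grouping independently of the incremental scan.
    """
    positions = hm_pooled.positions
    n_sites = positions.size
    if ehh_pairwise_oracle(hm_pooled.alleles, core, core) < cutoff:
        return 0.0, False
    total = 0.0
    edge = False
    for direction in (-1, 1):
        span = [core]
        j = core
        while True:
            jn = j + direction
            if jn < 0 or jn >= n_sites:
                edge = True
                break
            if abs(int(positions[jn]) - int(positions[j])) > max_gap:
                edge = True
                break
            if ehh_pairwise_oracle(hm_pooled.alleles, core, jn) < cutoff:
                break
            span.append(jn)
            j = jn
        es = [ehh_pairwise_oracle(hm_pop.alleles, core, t) for t in span]
        xs = [abs(int(positions[t]) - int(positions[core])) for t in span]
        total += np.trapezoid(es, xs)
    return float(total), edge


class TestEhh:
    def test_all_identical_gives_one(self):
        hm = HaplotypeMatrix(
            "c", [0, 10, 20], np.zeros((5, 3), dtype=np.uint8), ["a"] * 5
        )
        assert ehh(hm, 0, 2) == 1.0

    def test_all_distinct_gives_zero(self):
        alleles = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        hm = HaplotypeMatrix("c", [0, 10], alleles, ["a"] * 4)
        assert ehh(hm, 0, 1) == 0.0

    def test_one_pair_of_four(self):
        # span patterns {A, A, B, C}: one identical pair of six
        alleles = np.array([[0, 0], [0, 0], [0, 1], [1, 0]], dtype=np.uint8)
        hm = HaplotypeMatrix("c", [0, 10], alleles, ["a"] * 4)
        assert ehh(hm, 0, 1) == pytest.approx(1 / 6)

    def test_matches_pairwise_oracle_exactly(self, rng):
        """Grouping EHH equals the pairwise-comparison oracle on 100 sets."""
        for _ in range(100):
            n = int(rng.integers(2, 21))
            m = int(rng.integers(2, 51))
            hm = random_haplotype_matrix(rng, n_hap=n, n_sites=m, n_focal=n // 2)
            core = int(rng.integers(0, m))
            for target in range(m):
                assert ehh(hm, core, target) == ehh_pairwise_oracle(
                    hm.alleles, core, target
                )

    def test_non_increasing_with_span(self, rng):
        for _ in range(20):
            hm = random_haplotype_matrix(rng, n_hap=10, n_sites=25)
            core = 12
            right = [ehh(hm, core, t) for t in range(core, 25)]
            assert all(a >= b for a, b in zip(right, right[1:]))
            left = [ehh(hm, core, t) for t in range(core, -1, -1)]
            assert all(a >= b for a, b in zip(left, left[1:]))

    def test_single_haplotype_rejected(self):
        hm = HaplotypeMatrix("c", [0], np.zeros((1, 1), dtype=np.uint8), ["a"])
        with pytest.raises(ValueError):
            ehh(hm, 0, 0)


class TestIhh:
    def test_monomorphic_closed_form(self):
        positions = np.linspace(0, 10_000, 11).astype(int)
        alleles = np.zeros((6, 11), dtype=np.uint8)
        alleles[:, 5] = [0, 0, 0, 1, 1, 1]  # core site polymorphic, flanks identical
        hm = HaplotypeMatrix("c", positions, alleles, ["a"] * 6)
        # fully monomorphic spans: EHH never drops below cutoff, hits both edges
        mono = HaplotypeMatrix("c", positions, np.zeros((6, 11), dtype=np.uint8), ["a"] * 6)
        value, edge = ihh(mono, mono, core=5)
        assert value == pytest.approx(10_000)
        assert edge

    def test_pooled_below_cutoff_at_core_gives_zero(self):
        alleles = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8).T
        alleles = np.array([[0], [0], [1], [1]], dtype=np.uint8)
        hm = HaplotypeMatrix("c", [100], alleles, ["a"] * 4)
        # core homozygosity = (2*1 + 2*1)/(4*3) = 1/3 < cutoff 0.6
        value, edge = ihh(hm, hm, core=0, cutoff=0.6)
        assert value == 0.0
        assert not edge

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n, m = 6, 5
            positions = np.array([0, 100, 250, 400, 600])
            alleles = rng.integers(0, 2, size=(n, m)).astype(np.uint8)
            pops = np.array(["focal"] * 3 + ["reference"] * 3)
            pooled = HaplotypeMatrix("c", positions, alleles, pops)
            pop = HaplotypeMatrix("c", positions, alleles[:3], pops[:3])
            core = int(rng.integers(0, m))
            got, got_edge = ihh(pop, pooled, core, cutoff=0.05, max_gap=200_000)
            want, want_edge = ihh_brute_force(pop, pooled, core, 0.05, 200_000)
            assert got == pytest.approx(want, abs=1e-9)
            assert got_edge == want_edge

    def test_max_gap_truncates_with_edge_flag(self):
        positions = np.array([0, 100, 500_000])
        alleles = np.zeros((4, 3), dtype=np.uint8)
        hm = HaplotypeMatrix("c", positions, alleles, ["a"] * 4)
        value, edge = ihh(hm, hm, core=1, max_gap=1000)
        assert edge
        assert value == pytest.approx(100)  # only [0,100] integrated


class TestScan:
    def test_identical_populations_give_zero_raw(self, rng):
        half = rng.integers(0, 2, size=(6, 20)).astype(np.uint8)
        alleles = np.vstack([half, half])
        positions = np.sort(rng.choice(100_000, size=20, replace=False))
        hm = HaplotypeMatrix(
            "c", positions, alleles, ["focal"] * 6 + ["reference"] * 6
        )
        scores = xpehh_scan(hm, standardize=False)
        for s in scores:
            if s.xpehh_raw is not None:
                assert s.xpehh_raw == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_label_swap(self, rng):
        hm = random_haplotype_matrix(rng, n_hap=16, n_sites=60, span=400_000)
        swapped = HaplotypeMatrix(
            hm.chrom,
            hm.positions,
            hm.alleles,
            np.where(hm.hap_pop == "focal", "reference", "focal"),
        )
        a = xpehh_scan(hm, standardize=False)
        b = xpehh_scan(swapped, standardize=False)
        compared = 0
        for sa, sb in zip(a, b):
            if sa.xpehh_raw is not None:
                assert sb.xpehh_raw == pytest.approx(-sa.xpehh_raw, abs=1e-12)
                compared += 1
        assert compared > 10

    def test_kernel_and_numpy_paths_agree(self, rng):
        for _ in range(5):
            hm = random_haplotype_matrix(rng, n_hap=14, n_sites=40, span=300_000)
            fast = xpehh_scan(hm, standardize=False, use_kernel=True)
            slow = xpehh_scan(hm, standardize=False, use_kernel=False)
            for sa, sb in zip(fast, slow):
                assert sa.ihh_focal == pytest.approx(sb.ihh_focal, abs=1e-6)
                assert sa.ihh_ref == pytest.approx(sb.ihh_ref, abs=1e-6)
                assert sa.edge_flag == sb.edge_flag

    def test_standardization_moments(self, rng):
        hm = random_haplotype_matrix(rng, n_hap=20, n_sites=120, span=600_000)
        scores = xpehh_scan(hm)
        z = np.array([s.xpehh_z for s in scores if s.xpehh_z is not None])
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=0) - 1) < 1e-10

    def test_too_few_defined_scores_rejected(self):
        scores = []
        with pytest.raises(ValueError):
            standardize_scores(scores)

    def test_requires_two_populations(self, rng):
        hm = random_haplotype_matrix(rng, n_hap=8, n_sites=10, n_focal=8)
        with pytest.raises(ValueError, match="2 population"):
            xpehh_scan(hm)
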