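import numpy as np
import pytest

from sweepscan.simulate import (
    SweepSimConfig,
    _ancestral_pool,
    _evolve,
    simulate_gene_sites,
    simulate_two_pop_sweep,
)

SMALL = dict(N=60, T=40, L=500_000, M=300, r_bp=1e-8, sweep_pos=250_000)


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [("N", 5), ("T", 0), ("s", 1.5), ("s", -0.1), ("sweep_pos", 500_000), ("M", 1), ("r_bp", -1e-8)],
    )
    def test_invalid_rejected(self, field, value):
        kwargs = dict(SMALL, s=0.1)
        kwargs[field] = value
        with pytest.raises(ValueError):
            SweepSimConfig(**kwargs)


class TestSweepSim:
    def test_determinism(self):
        cfg = SweepSimConfig(**SMALL, s=0.1, seed=11)
        a, ta = simulate_two_pop_sweep(cfg)
        b, tb = simulate_two_pop_sweep(cfg)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)
        assert ta == tb

    def test_shapes_and_labels(self):
        cfg = SweepSimConfig(**SMALL, s=0.0, seed=3)
        hm, truth = simulate_two_pop_sweep(cfg)
        assert hm.n_haplotypes == 4 * cfg.N  # 2N haplotypes per population
        assert sorted(set(hm.hap_pop)) == ["focal", "reference"]
        assert (hm.hap_pop == "focal").sum() == 2 * cfg.N
        assert truth.s == 0.0
        # monomorphic sites dropped: every retained column is polymorphic
        sums = hm.alleles.sum(axis=0)
        assert ((sums > 0) & (sums < hm.n_haplotypes)).all()

    def test_selection_raises_focal_frequency(self):
        """Directional selection lifts the selected allele above its
        neutrally drifting frequency in the reference population."""
        wins = 0
        for rep in range(20):
            cfg = SweepSimConfig(N=500, T=200, s=0.1, M=2000, L=2_500_000, seed=300 + rep)
            _, truth = simulate_two_pop_sweep(cfg)
            wins += truth.focal_final_freq > truth.ref_final_freq
        assert wins >= 18

    def test_heterozygosity_decay_matches_wright_fisher(self):
        """Neutral expected heterozygosity decays by (1 - 1/2N)^T."""
        N, T = 50, 30
        ratios = []
        for rep in range(25):
            cfg = SweepSimConfig(
                N=N, T=T, s=0.0, L=100_000, M=200, r_bp=0.0,
                sweep_pos=50_000, seed=900 + rep,
            )
            rng = np.random.default_rng(cfg.seed)
            positions, anc, _ = _ancestral_pool(cfg, rng)
            p0 = anc.mean(axis=0)
            h0 = (2 * p0 * (1 - p0)).mean()
            out = _evolve(anc.copy(), positions, cfg, np.random.default_rng(cfg.seed + 1), None)
            p1 = out.mean(axis=0)
            h1 = (2 * p1 * (1 - p1)).mean()
            ratios.append(h1 / h0)
        expected = (1 - 1 / (2 * N)) ** T
        assert np.mean(ratios) == pytest.approx(expected, abs=0.05)

    def test_neutral_exchangeability_of_labels(self):
        """Under s=0 the two populations are exchangeable: swapping labels
        leaves window-significance counts statistically indistinguishable
        (sign test over replicates)."""
        from sweepscan.windows import summarize
        from sweepscan.xpehh import xpehh_scan

        diffs = []
        for rep in range(10):
            cfg = SweepSimConfig(
                N=50, T=30, L=400_000, M=250, s=0.0, sweep_pos=200_000, seed=40 + rep
            )
            hm, _ = simulate_two_pop_sweep(cfg)
            counts = {}
            for focal in ("focal", "reference"):
                scores = xpehh_scan(hm, focal=focal)
                ws, _ = summarize(
                    [(s.chrom, s.pos, s.xpehh_z) for s in scores],
                    mode="xpehh", alpha=0.1,
                )
                counts[focal] = sum(w.significant for w in ws)
            diffs.append(counts["focal"] - counts["reference"])
        nonzero = [d for d in diffs if d != 0]
        pos = sum(d > 0 for d in nonzero)
        # two-sided sign test at alpha ~ 0.02 for n <= 10
        if nonzero:
            n = len(nonzero)
            from scipy.stats import binomtest

            assert binomtest(pos, n, 0.5).pvalue > 0.02

    def test_restart_counted_and_reference_untouched(self):
        """A restarted focal run must not perturb the reference stream."""
        cfg_sel = SweepSimConfig(**SMALL, s=0.2, seed=77)
        cfg_neu = SweepSimConfig(**SMALL, s=0.0, seed=77)
        hm_sel, truth_sel = simulate_two_pop_sweep(cfg_sel)
        hm_neu, _ = simulate_two_pop_sweep(cfg_neu)
        ref_sel = hm_sel.alleles[hm_sel.hap_pop == "reference"]
        ref_neu = hm_neu.alleles[hm_neu.hap_pop == "reference"]
        # same seed -> identical reference evolution regardless of restarts,
        # but retained (polymorphic) site sets differ; compare via positions
        common = np.intersect1d(hm_sel.positions, hm_neu.positions)
        i_sel = np.searchsorted(hm_sel.positions, common)
        i_neu = np.searchsorted(hm_neu.positions, common)
        assert np.array_equal(ref_sel[:, i_sel], ref_neu[:, i_neu])


class TestGeneSites:
    def test_null_truth_empty_and_determinism(self):
        m1, truth = simulate_gene_sites(n_sites=20, seed=9)
        m2, _ = simulate_gene_sites(n_sites=20, seed=9)
        assert truth == []
        assert m1.equals(m2)

    def test_infinite_odds_fixes_focal_breed(self):
        m, _ = simulate_gene_sites(
            n_sites=5, n_hap=15,
            enriched_sites=[(2, "Landrace", "Y", float("inf"))], seed=4,
        )
        landrace = m[m.breed == "Landrace"]
        assert (landrace["site_3"] == "Y").all()

    def test_out_of_range_site_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            simulate_gene_sites(n_sites=5, enriched_sites=[(7, "Berkshire", "Y", 5.0)])

    def test_odds_must_exceed_one(self):
        with pytest.raises(ValueError, match="odds"):
            simulate_gene_sites(n_sites=5, enriched_sites=[(1, "Berkshire", "Y", 1.0)])

    def test_breed_block_structure(self):
        m, _ = simulate_gene_sites(n_sites=3, n_hap=4, seed=0)
        assert list(m["breed"]) == ["Berkshire"] * 4 + ["Landrace"] * 4 + ["Yorkshire"] * 4
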