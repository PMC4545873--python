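import math

import numpy as np
import pytest
from scipy.stats import binom

from sweepscan.datatypes import FrequencyTable
from sweepscan.xpclr import (
    clr_scan,
    default_s_grid,
    escape_probability,
    estimate_omega,
    frequency_table,
    simulate_frequencies,
    site_loglik,
    sweep_duration,
)

from conftest import random_haplotype_matrix


def mc_loglik_oracle(p_ref, k, n, omega, model, c, rng, n_draws=200_000):
    """Monte-Carlo integration of the same likelihood; returns (ll, se_of_p)."""
    q = rng.normal(p_ref, math.sqrt(omega * p_ref * (1 - p_ref)), n_draws)
    q = np.clip(q, 0.0, 1.0)
    if model == "sweep":
        on_sweep = rng.random(n_draws) < q
        q = np.where(on_sweep, 1 - c + c * q, c * q)
    vals = binom.pmf(k, n, q)
    return float(vals.mean()), float(vals.std() / math.sqrt(n_draws))


class TestOmega:
    def test_zero_when_frequencies_match(self):
        p = np.linspace(0.1, 0.9, 200)
        n = 50
        ft = FrequencyTable("c", np.arange(200), p, (p * n).round().astype(int), np.full(200, n))
        # k/n == p_ref exactly only where p*n is integral; build that way
        p = np.round(p * n) / n
        ft = FrequencyTable("c", np.arange(200), p, (p * n).round().astype(int), np.full(200, n))
        assert estimate_omega(ft) == pytest.approx(0.0, abs=1e-15)

    def test_single_site_contribution(self):
        ft = FrequencyTable("c", [0], [0.5], [6], [10])
        # (0.6 - 0.5)^2 / 0.25 = 0.04
        assert estimate_omega(ft, min_sites=1) == pytest.approx(0.04)

    def test_too_few_eligible_sites(self):
        ft = FrequencyTable("c", [0, 1], [0.01, 0.99], [0, 10], [10, 10])
        with pytest.raises(ValueError, match="eligible|sites"):
            estimate_omega(ft)

    def test_recovery_from_generative_law(self, rng):
        """omega within +-0.01 of the generating 0.05 at 5000 sites."""
        ft = simulate_frequencies(5000, 0.05, n_focal=1000, L=50_000_000, rng=rng)
        assert estimate_omega(ft) == pytest.approx(0.05, abs=0.01)


class TestEscapeProbability:
    def test_zero_distance(self):
        assert escape_probability(0, 0.1, 1e-8, 500) == 0.0

    def test_far_distance_approaches_one(self):
        assert escape_probability(1e12, 0.1, 1e-8, 500) == pytest.approx(1.0)

    def test_plug_in_value(self):
        # t_s = ln(100)/0.1 ~ 46.05; c = 1 - exp(-1e-8 * 1e6 * t_s)
        c = escape_probability(1e6, 0.1, 1e-8, 500)
        assert c == pytest.approx(1 - math.exp(-0.46052), abs=1e-4)

    def test_small_2ns_rejected(self):
        with pytest.raises(ValueError, match="2Ns"):
            escape_probability(1000, 1e-4, 1e-8, 500)

    def test_composite_behaviour_matches_formula(self):
        """c as implemented equals 1-exp(-r d ln(2Ns)/s) on a grid; c falls
        as t_s*r*d falls, while t_s itself decreases in s."""
        r_bp, N, d = 1e-8, 500, 200_000
        s_vals = np.geomspace(0.005, 0.5, 12)
        ts = [sweep_duration(s, N) for s in s_vals]
        assert all(a > b for a, b in zip(ts, ts[1:]))  # t_s decreasing in s
        for s, t in zip(s_vals, ts):
            expected = 1 - math.exp(-r_bp * d * t)
            assert escape_probability(d, s, r_bp, N) == pytest.approx(expected, rel=1e-12)


class TestSiteLoglik:
    def test_sweep_collapses_to_neutral_at_c_one(self, rng):
        for _ in range(10):
            p = rng.uniform(0.1, 0.9)
            k, n = int(rng.integers(0, 21)), 20
            ln = site_loglik(p, k, n, 0.08, model="neutral")
            ls = site_loglik(p, k, n, 0.08, model="sweep", c=1.0)
            assert ls == pytest.approx(ln, abs=1e-10)

    def test_degenerate_drift_approaches_binomial(self):
        ll = site_loglik(0.5, 5, 10, omega=1e-3, model="neutral")
        assert ll == pytest.approx(math.log(binom.pmf(5, 10, 0.5)), abs=5e-3)

    def test_matches_mc_oracle(self, rng):
        """Instances are drawn from the model's own generative process so
        the integral is never tail-dominated (where a plain MC estimate and
        its standard error both break down)."""
        for model in ("neutral", "sweep"):
            for _ in range(10):
                p = rng.uniform(0.1, 0.9)
                omega = rng.uniform(0.02, 0.2)
                c = rng.uniform(0.05, 0.95)
                n = 20
                q = float(np.clip(rng.normal(p, math.sqrt(omega * p * (1 - p))), 0, 1))
                if model == "sweep":
                    q = 1 - c + c * q if rng.random() < q else c * q
                k = int(rng.binomial(n, q))
                ll = site_loglik(p, k, n, omega, model=model, c=c)
                est, se = mc_loglik_oracle(p, k, n, omega, model, c, rng)
                assert abs(math.exp(ll) - est) < 3 * se

    def test_self_convergence_in_quadrature_density(self, rng):
        """Refining the quadrature grid does not move the log-likelihood,
        including tail-dominated instances where MC oracles are unreliable."""
        for k in (0, 10, 20):
            a = site_loglik(0.214, k, 20, 0.137, model="neutral", n_quad=512)
            b = site_loglik(0.214, k, 20, 0.137, model="neutral", n_quad=8192)
            assert a == pytest.approx(b, abs=2e-4)

    def test_invalid_omega_rejected(self):
        with pytest.raises(ValueError):
            site_loglik(0.5, 5, 10, omega=0.0)


class TestClrScan:
    def small_ft(self, rng, sweep=False):
        return simulate_frequencies(
            200, 0.05, n_focal=20, L=500_000, rng=rng,
            sweep_pos=250_000 if sweep else None, s=0.05 if sweep else None,
        )

    def test_clr_nonnegative_everywhere(self, rng):
        ft = self.small_ft(rng)
        pts = clr_scan(ft, 0.05)
        assert all(p.clr >= 0 for p in pts if p.clr is not None)

    def test_neutral_data_floors_many_points_at_zero(self, rng):
        ft = self.small_ft(rng)
        pts = [p for p in clr_scan(ft, 0.05) if p.clr is not None]
        frac_zero = sum(p.clr == 0 for p in pts) / len(pts)
        assert frac_zero > 0.2

    def test_empty_window_emits_undefined(self, rng):
        positions = np.array([0, 1000, 480_000, 481_000])
        ft = FrequencyTable("c", positions, [0.5] * 4, [10] * 4, [20] * 4)
        pts = clr_scan(ft, 0.05, grid_spacing=2500, window_radius=12_500)
        middle = [p for p in pts if 100_000 < p.pos < 400_000]
        assert middle and all(p.clr is None for p in middle)

    def test_locality(self, rng):
        """Removing a site outside every window leaves near-side clr unchanged."""
        ft = self.small_ft(rng)
        pts_full = clr_scan(ft, 0.05)
        # drop the last site; grid points whose window never saw it are unchanged
        ft2 = FrequencyTable(
            "c", ft.positions[:-1], ft.p_ref[:-1], ft.k_focal[:-1], ft.n_focal[:-1]
        )
        pts_drop = clr_scan(ft2, 0.05)
        cut = ft.positions[-1] - 12_500
        for a, b in zip(pts_full, pts_drop):
            if a.pos < cut and a.clr is not None:
                assert b.clr == pytest.approx(a.clr, abs=1e-9)
                assert b.s_hat == a.s_hat

    def test_s_hat_in_grid_and_tie_toward_smaller(self, rng):
        grid = default_s_grid()
        ft = self.small_ft(rng, sweep=True)
        pts = clr_scan(ft, 0.05)
        for p in pts:
            if p.s_hat is not None:
                assert any(np.isclose(p.s_hat, grid))

    def test_sweep_localization(self, rng):
        """Argmax grid point lands in the true sweep's 25-kb window or an
        adjacent one in most replicates."""
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(7000 + rep)
            ft = simulate_frequencies(
                500, 0.05, n_focal=50, L=1_000_000, rng=r, sweep_pos=500_000, s=0.05
            )
            pts = clr_scan(
                ft, estimate_omega(ft),
                window_radius=100_000, grid_spacing=5000, n_quad=256,
            )
            best = max((p for p in pts if p.clr is not None), key=lambda p: p.clr)
            hits += abs(best.pos // 25_000 - 500_000 // 25_000) <= 1
        assert hits >= 7


class TestFrequencyTable:
    def test_from_haplotype_matrix(self, rng):
        hm = random_haplotype_matrix(rng, n_hap=10, n_sites=15, n_focal=4)
        ft = frequency_table(hm, focal="focal")
        ref_rows = hm.alleles[4:]
        assert np.allclose(ft.p_ref, ref_rows.mean(axis=0))
        assert np.array_equal(ft.k_focal, hm.alleles[:4].sum(axis=0))
        assert (ft.n_focal == 4).all()
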