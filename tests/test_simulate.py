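"""Founder-demography simulation against closed-form and enumeration oracles."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

from patchdemes.colonization import p_single, zt_poisson_mean
from patchdemes.simulate import (
    FounderSimConfig, mean_founders_exact, mean_founders_proliferative,
    sample_zt_poisson, simulate_fig_experiment, simulate_patches,
)


class TestZeroTruncatedSampling:
    def test_degenerate_limit_always_one(self, rng):
        assert np.all(sample_zt_poisson(0.0, 1000, rng) == 1)

    def test_sample_mean_matches_closed_form(self, rng):
        draws = sample_zt_poisson(3.9, 10 ** 6, rng)
        mu = zt_poisson_mean(3.9)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - mu) < 3 * se

    def test_pmf_matches_closed_form(self, rng):
        lam = 2.0
        draws = sample_zt_poisson(lam, 200_000, rng)
        ks = np.arange(1, 11)
        expected_p = poisson.pmf(ks, lam) / -math.expm1(-lam)
        obs = np.bincount(draws, minlength=12)[1:11]
        obs = np.append(obs, draws.size - obs.sum())
        exp = np.append(expected_p, 1 - expected_p.sum()) * draws.size
        assert chisquare(obs, exp).pvalue > 1e-4

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_zt_poisson(-1.0, 10, rng)


class TestSimulatePatches:
    def test_zero_rate_all_patches_empty(self):
        out = simulate_patches(FounderSimConfig(0.0, 3.9, n_patches=200))
        assert all(p.n_founders == 0 for p in out)

    def test_bit_reproducible_under_seed(self):
        cfg = FounderSimConfig(0.5, 2.0, n_patches=500, seed=7)
        a, b = simulate_patches(cfg), simulate_patches(cfg)
        assert all(x == y for x, y in zip(a, b))

    def test_realization_bookkeeping(self):
        for p in simulate_patches(FounderSimConfig(1.0, 3.0,
                                                   n_patches=300, seed=1)):
            assert p.n_founders == sum(p.founder_groups)
            assert p.n_females + p.n_males == p.n_founders
            assert all(g >= 1 for g in p.founder_groups)
            assert p.proliferative == (p.n_females >= 1 and p.n_males >= 1)

    def test_empty_fraction_matches_poisson_zero_class(self):
        n = 200_000
        out = simulate_patches(FounderSimConfig(0.29, 3.9, n_patches=n, seed=3))
        frac = sum(1 for p in out if p.n_founders == 0) / n
        expect = math.exp(-0.29)
        assert abs(frac - expect) < 3 * math.sqrt(expect * (1 - expect) / n)

    def test_single_worm_fraction_matches_inference_model(self):
        """Occupied patches with N = 1 occur at the single-worm probability
        used by the likelihood inference (cross-module consistency)."""
        lc, ld, n = 0.29, 3.9, 400_000
        out = simulate_patches(FounderSimConfig(lc, ld, n_patches=n, seed=9))
        occupied = [p for p in out if p.n_founders > 0]
        frac = sum(1 for p in occupied if p.n_founders == 1) / len(occupied)
        p1 = p_single(lc, ld)
        assert abs(frac - p1) < 3 * math.sqrt(p1 * (1 - p1) / len(occupied))

    def test_mean_founders_per_patch(self):
        lc, ld = 0.8, 2.5
        out = simulate_patches(FounderSimConfig(lc, ld, n_patches=200_000,
                                                seed=11))
        n = np.array([p.n_founders for p in out], dtype=float)
        expect = lc * zt_poisson_mean(ld)
        assert abs(n.mean() - expect) < 3 * n.std() / math.sqrt(n.size)


class TestProliferativeFounders:
    def test_mc_agrees_with_enumeration_oracle_grid(self):
        for lc in (0.3, 1.0):
            for ld in (0.5, 2.0, 3.9):
                cfg = FounderSimConfig(lc, ld, 0.5, n_patches=300_000,
                                       seed=int(lc * 10 + ld))
                mc, se = mean_founders_proliferative(cfg)
                exact = mean_founders_exact(lc, ld, 0.5)
                assert abs(mc - exact) < 3 * se + 1e-9

    def test_one_dauer_groups_against_enumeration(self):
        cfg = FounderSimConfig(1.5, 0.0, 0.5, n_patches=200_000, seed=2)
        mc, se = mean_founders_proliferative(cfg)
        exact = mean_founders_exact(1.5, 0.0, 0.5)
        assert abs(mc - exact) < 3 * se

    def test_sex_ratio_symmetry(self):
        a = mean_founders_exact(0.29, 3.9, 0.2)
        b = mean_founders_exact(0.29, 3.9, 0.8)
        assert math.isclose(a, b, rel_tol=1e-12)

    def test_degenerate_sex_ratio_rejected(self):
        with pytest.raises(ValueError):
            mean_founders_exact(0.29, 3.9, 1.0)
        with pytest.raises(ValueError):
            FounderSimConfig(0.29, 3.9, female_fraction=1.0, n_patches=10)

    def test_no_proliferative_patches_is_advisory_error(self):
        cfg = FounderSimConfig(0.01, 0.0, 0.5, n_patches=10, seed=0)
        with pytest.raises(ValueError, match="n_patches"):
            mean_founders_proliferative(cfg)

    def test_truncation_warning(self):
        with pytest.warns(RuntimeWarning, match="tail"):
            mean_founders_exact(5.0, 8.0, 0.5, n_max=60)


class TestFigExperiment:
    def test_species_colonize_independently(self, rng):
        cnt = simulate_fig_experiment(
            1, [("a", 0.8, 2.0), ("b", 0.8, 2.0)],
            n_replicates=100_000, rng=rng)[:, 0, :]
        pres = (cnt > 0).astype(float)
        r = np.corrcoef(pres[:, 0], pres[:, 1])[0, 1]
        assert abs(r) < 0.02

    def test_occupancy_matches_poisson_zero_class(self, rng):
        lam = 1.2
        cnt = simulate_fig_experiment(74, [("a", lam, 3.9)],
                                      n_replicates=5_000, rng=rng)
        occ = (cnt[:, :, 0] > 0).mean(axis=1) * 74
        # 74 * (1 - e^-1.2) ~ 51.7 occupied figs on average
        assert abs(occ.mean() - 74 * -math.expm1(-lam)) < 3 * occ.std() / 70

    def test_invalid_fig_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_fig_experiment(0, [("a", 1.0, 1.0)])
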