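import math

import numpy as np
import pytest
from scipy import stats

from perioscope import (
    Periodogram,
    detect,
    fisher_g_pvalue,
    fishers_g,
    periodogram,
    rank_periods,
    simulate_genome,
    simulate_profile,
    bin_profile,
    ProfileSpec,
)
from tests_helpers import dft_periodogram_oracle, fisher_g_null_draws, make_series


class TestPeriodogram:
    def test_pure_cosine_closed_form(self):
        # unit-amplitude sinusoid at k: I_k = A^2 n / 4, all other ordinates 0
        n = 64
        t = np.arange(n)
        s = periodogram(make_series(np.cos(2 * np.pi * 6 * t / n)))
        pg = s
        assert pg.ordinates[5] == pytest.approx(16.0, abs=1e-9)
        others = np.delete(pg.ordinates, 5)
        assert np.all(others < 1e-9)

    def test_constant_series_all_zero(self):
        pg = periodogram(make_series(np.full(32, 3.0)))
        assert np.allclose(pg.ordinates, 0.0)

    def test_matches_dft_sum_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        pg = periodogram(make_series(x))
        oracle = dft_periodogram_oracle(x)
        assert np.allclose(pg.ordinates, oracle, rtol=1e-9, atol=1e-12)

    def test_parseval(self):
        rng = np.random.default_rng(1)
        for n in (33, 64):
            x = rng.normal(size=n)
            pg = periodogram(make_series(x))
            xc = x - x.mean()
            two_sided = 2 * pg.ordinates.sum()
            if n % 2 == 0:
                two_sided -= pg.ordinates[-1]  # Nyquist appears once
            assert two_sided == pytest.approx(float(xc @ xc), rel=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        p1 = periodogram(make_series(x))
        p2 = periodogram(make_series(3.0 * x))
        assert np.allclose(p2.ordinates, 9.0 * p1.ordinates, rtol=1e-12)
        g1, pv1 = fishers_g(p1)
        g2, pv2 = fishers_g(p2)
        assert g1 == pytest.approx(g2, rel=1e-12)
        assert pv1 == pytest.approx(pv2, rel=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=48)
        p1 = periodogram(make_series(x))
        p2 = periodogram(make_series(np.roll(x, 13)))
        assert np.allclose(p1.ordinates, p2.ordinates, atol=1e-9)

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="too short"):
            periodogram(make_series([1.0, 2.0]))
        bad = make_series(np.ones(16))
        bad.values[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            periodogram(bad)
        uneven = make_series(np.arange(16.0))
        uneven.centers[5] += 100.0
        with pytest.raises(ValueError, match="evenly"):
            periodogram(uneven)


class TestRankPeriods:
    def test_priority_order_mirrors_two_component_series(self):
        n = 600
        t = np.arange(n)
        x = 2 * np.sin(2 * np.pi * t / n) + 1 * np.sin(2 * np.pi * 6 * t / n)
        pg = periodogram(make_series(x))
        ranked = rank_periods(pg, length_bp=n * 1000, depth=2)
        assert ranked[0].k == 1 and ranked[1].k == 6

    def test_tie_breaks_to_smaller_k(self):
        pg = Periodogram(n=20, ordinates=np.array([1.0, 5.0, 2.0, 5.0, 0.5,
                                                   0.1, 0.1, 0.1, 0.1, 0.1]))
        ranked = rank_periods(pg, length_bp=20_000, depth=3)
        assert [r.k for r in ranked] == [2, 4, 3]

    def test_wavelength_rounding(self):
        pg = Periodogram(n=4642, ordinates=np.zeros(2321))
        pg.ordinates[5] = 10.0
        ranked = rank_periods(pg, length_bp=4_642_000, depth=1)
        assert ranked[0].k == 6
        assert ranked[0].wavelength_bp == 773_667

    def test_depth_truncated(self):
        pg = Periodogram(n=10, ordinates=np.arange(5.0) + 1)
        assert len(rank_periods(pg, 10_000, depth=99)) == 5


class TestFishersG:
    def test_equal_ordinates_give_p_one(self):
        # m=3, all equal: g = 1/3 and 3(2/3)^2 - 3(1/3)^2 + 0 = 1
        assert fisher_g_pvalue(1.0 / 3.0, 3) == pytest.approx(1.0, abs=1e-12)

    def test_m3_g09_exact(self):
        assert fisher_g_pvalue(0.9, 3) == pytest.approx(0.03, abs=1e-12)

    def test_statistic_definition(self):
        pg = Periodogram(n=9, ordinates=np.array([4.0, 1.0, 1.0, 2.0]))
        g, p = fishers_g(pg)  # m = 4, uses all four ordinates
        assert g == pytest.approx(0.5)
        assert p == pytest.approx(fisher_g_pvalue(0.5, 4))

    def test_nyquist_excluded_for_even_n(self):
        ords = np.array([1.0, 2.0, 3.0, 100.0])
        pg = Periodogram(n=8, ordinates=ords)   # m = 3: Nyquist ordinate dropped
        g, _ = fishers_g(pg)
        assert g == pytest.approx(3.0 / 6.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fishers_g(Periodogram(n=16, ordinates=np.zeros(8)))

    def test_p_uniform_under_white_noise(self):
        # KS over 2000 white-noise series of length 101
        rng = np.random.default_rng(12345)
        pvals = []
        for _ in range(2000):
            pg = periodogram(make_series(rng.normal(size=101)))
            pvals.append(fishers_g(pg)[1])
        ks = stats.kstest(pvals, "uniform").statistic
        crit_1pct = 1.628 / math.sqrt(2000)
        assert ks < crit_1pct

    def test_matches_small_monte_carlo_null(self):
        rng = np.random.default_rng(99)
        m, n_draws = 25, 20_000
        g = fisher_g_null_draws(m, n_draws, rng)
        for g0 in (0.15, 0.25, 0.35):
            p_exact = fisher_g_pvalue(g0, m)
            p_emp = float((g > g0).mean())
            se = math.sqrt(p_exact * (1 - p_exact) / n_draws)
            assert abs(p_emp - p_exact) < 4 * se


class TestDetect:
    def test_six_period_profile(self, small_genome, small_spec):
        prof = simulate_profile(small_genome, small_spec, "s")
        series = bin_profile(prof, small_genome, 10_000, 1_000)
        res = detect(series)
        assert res.dominant_k == 6
        assert res.p_value < 1e-6
        assert res.m == (res.n - 1) // 2

    def test_pure_noise_has_no_stable_top_k(self):
        tops = set()
        for seed in range(6):
            spec = ProfileSpec(length_bp=200_000, n_genes=300, k_true=0,
                               a_true=0.0, noise_sd=1.0, mean_gene_bp=300,
                               seed=seed)
            gm = simulate_genome(spec)
            prof = simulate_profile(gm, spec, "s")
            series = bin_profile(prof, gm, 4_000, 1_000)
            tops.add(detect(series).dominant_k)
        assert len(tops) > 1

    def test_constant_series_errors(self):
        with pytest.raises(ValueError):
            detect(make_series(np.full(64, 2.0)))
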