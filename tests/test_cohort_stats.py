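import math

import numpy as np
import pytest

from perioscope import (
    ExpressionProfile,
    GeneRecord,
    GenomeMap,
    TrackProfile,
    build_cohort,
    param_growth_matrix,
    pearson_t,
    track_expression_correlation,
)
from perioscope.cohort_stats import bin_track, lag1_autocorr, windowed_correlation
from perioscope.harmonic_fit import ReplicateSummary
from perioscope.spatial_profile import bin_profile, zscore_series


def summary(comb, a, b=0.2, c=5.0):
    return ReplicateSummary(comb, a, 0.01, b, 0.01, c, 0.01, 3, 60_000.0)


def meta(r=0.5, phase="exponential", env="regular"):
    return {"strain": "s", "environment": env, "growth_phase": phase, "growth_rate": r}


class TestPearsonT:
    def test_hand_computed_example(self):
        res = pearson_t([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)
        assert res.t == pytest.approx(0.6 * math.sqrt(2) / 0.8, rel=1e-9)
        assert res.df == 2

    def test_perfect_correlation_flagged(self):
        x = np.arange(5.0)
        res = pearson_t(x, 2 * x)
        assert res.rho == pytest.approx(1.0)
        assert res.p == 0.0 and res.perfect
        assert math.isinf(res.t)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson_t(x, y) == pearson_t(y, x)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r1 = pearson_t(x, y)
        r2 = pearson_t(3.0 * x + 10.0, y)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)

    def test_contracts(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_t([1, 2], [3, 4])
        with pytest.raises(ValueError, match="constant"):
            pearson_t([1, 1, 1], [1, 2, 3])

    def test_type_one_error_rate(self):
        # independent N(0,1) pairs at the cohort's n=42: rejection near alpha
        rng = np.random.default_rng(2024)
        rejections = sum(
            pearson_t(rng.normal(size=42), rng.normal(size=42)).p < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065


class TestBuildCohort:
    def test_phase_filter(self):
        summaries = [summary(f"c{i}", 0.3) for i in range(5)]
        md = {f"c{i}": meta(phase="exponential" if i < 3 else "stress-response")
              for i in range(5)}
        cohort = build_cohort(summaries, md)
        assert len(cohort) == 3

    def test_duplicate_combination_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_cohort([summary("c1", 0.3), summary("c1", 0.4)], {"c1": meta()})

    def test_empty_after_filter_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_cohort([summary("c1", 0.3)], {"c1": meta(phase="stress-response")})

    def test_missing_growth_rate_excluded(self):
        md = {"c1": meta(), "c2": {"growth_phase": "exponential", "growth_rate": None}}
        cohort = build_cohort([summary("c1", 0.3), summary("c2", 0.4)], md)
        assert list(cohort["combination_id"]) == ["c1"]


class TestMatrix:
    def _cohort(self, rng, n=20, slope=0.2):
        rows, md = [], {}
        for i in range(n):
            r = float(rng.uniform(0.2, 1.0))
            rows.append(summary(f"c{i}", 0.1 + slope * r,
                                b=float(rng.uniform()), c=float(rng.normal(5, 0.1))))
            md[f"c{i}"] = meta(r=r, env=("regular", "temperature")[i % 2])
        return build_cohort(rows, md)

    def test_exact_linear_coupling(self):
        rng = np.random.default_rng(3)
        cohort = self._cohort(rng)
        m = param_growth_matrix(cohort)
        assert m.get("a", "r").rho == pytest.approx(1.0)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(4)
        m = param_growth_matrix(self._cohort(rng))
        assert m.get("a", "r").rho == m.get("r", "a").rho
        assert m.get("b", "b").rho == 1.0
        assert m.marginals  # per-environment marginal distributions present

    def test_permutation_null_centres_on_zero(self):
        rng = np.random.default_rng(5)
        cohort = self._cohort(rng, n=30)
        rhos = []
        a = cohort["mean_a"].to_numpy()
        r = cohort["r"].to_numpy().copy()
        for _ in range(200):
            rng.shuffle(r)
            rhos.append(pearson_t(a, r).rho)
        assert abs(np.mean(rhos)) < 0.05


class TestTrackCorrelation:
    def _setup(self):
        rng = np.random.default_rng(6)
        length = 60_000
        genes = []
        vals = {}
        for i, pos in enumerate(sorted(rng.choice(np.arange(1, length, 20), 400,
                                                  replace=False))):
            genes.append(GeneRecord(f"g{i}", int(pos), int(pos) + 10))
            vals[f"g{i}"] = float(np.sin(2 * np.pi * 3 * pos / length) + rng.normal(0, 0.1))
        gm = GenomeMap("g", length, True, genes)
        prof = ExpressionProfile("s", "g", vals)
        return gm, prof

    def _track_from_series(self, series, gm, transform):
        step = gm.length_bp // series.n
        ivs = [(int(c) + 1, int(c) + step, transform(v))
               for c, v in zip(series.centers, series.values)]
        return TrackProfile(gm.genome_id, ivs)

    def test_affine_series_correlate_perfectly(self):
        from tests_helpers import make_series
        rng = np.random.default_rng(10)
        v = rng.normal(size=120)
        res = windowed_correlation(
            zscore_series(make_series(v)),
            zscore_series(make_series(2.0 * v + 1.0)),
        )
        assert res.nominal.rho == pytest.approx(1.0)
        assert res.nominal.perfect

    def test_track_binning_recovers_interval_values(self):
        gm, prof = self._setup()
        series = bin_profile(prof, gm, 1_000, 1_000)
        track = self._track_from_series(series, gm, lambda v: 2.0 * v + 1.0)
        binned = bin_track(track, gm, 1_000, 1_000)
        # step-aligned intervals: each window mixes two abutting intervals,
        # so the binned track is a 2-tap moving average of the affine signal
        res = windowed_correlation(zscore_series(series), zscore_series(binned))
        assert res.nominal.rho > 0.9

    def test_full_pipeline_signs(self):
        gm, prof = self._setup()
        series = bin_profile(prof, gm, 6_000, 1_000)
        up = self._track_from_series(series, gm, lambda v: v)
        down = self._track_from_series(series, gm, lambda v: -v)
        pos = track_expression_correlation(prof, up, gm, 6_000, 1_000)
        neg = track_expression_correlation(prof, down, gm, 6_000, 1_000)
        assert pos.nominal.rho > 0.95
        assert neg.nominal.rho < -0.95
        assert neg.adjusted_p >= neg.nominal.p  # autocorrelation adjustment widens

    def test_genome_mismatch_rejected(self):
        gm, prof = self._setup()
        track = TrackProfile("other", [(1, 10, 1.0)])
        with pytest.raises(ValueError, match="genome"):
            track_expression_correlation(prof, track, gm)

    def test_lag1_autocorr_range(self):
        rng = np.random.default_rng(7)
        white = rng.normal(size=500)
        smooth = np.convolve(white, np.ones(50) / 50, mode="same")
        assert abs(lag1_autocorr(white)) < 0.2
        assert lag1_autocorr(smooth) > 0.9

    def test_overlap_inflation_detected(self):
        # windowed white noise vs independent windowed white noise:
        # nominal p is anticonservative, adjusted p is not
        rng = np.random.default_rng(8)
        from tests_helpers import make_series
        nominal_small, adjusted = 0, []
        for _ in range(60):
            a = np.convolve(rng.normal(size=600), np.ones(60) / 60, mode="same")
            b = np.convolve(rng.normal(size=600), np.ones(60) / 60, mode="same")
            res = windowed_correlation(make_series(a), make_series(b))
            nominal_small += res.nominal.p < 0.05
            adjusted.append(res.adjusted_p)
        assert nominal_small / 60 > 0.20
        assert np.mean(np.array(adjusted) < 0.05) < 0.15
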