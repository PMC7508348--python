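"""Cohort-level statistics: growth-rate correlations of the fitted
periodicity parameters, and window-wise correlation of expression with a
genomic binding track.

The cohort table joins per-combination replicate means of (a, b_norm, c)
to the measured exponential-phase growth rate r (per hour).  Correlations
are sample Pearson coefficients with two-sided t-tests:

    t = rho * sqrt(n - 2) / sqrt(1 - rho^2),   df = n - 2.

Window-wise track correlations use heavily overlapping sliding windows
(100 kb windows every 1 kb), so consecutive points are strongly
autocorrelated and the nominal t-test overstates significance.  Alongside
the nominal p the functions report an adjusted p based on the effective
sample size n_eff = n (1 - phi) / (1 + phi), with phi the larger lag-1
autocorrelation of the two series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    ENVIRONMENT_CATEGORIES,
    ExpressionProfile,
    GenomeMap,
    TrackProfile,
)
from .harmonic_fit import ReplicateSummary
from .spatial_profile import (
    DEFAULT_STEP_BP,
    DEFAULT_WINDOW_BP,
    SpatialSeries,
    bin_profile,
    zscore_series,
)

logger = logging.getLogger(__name__)

PARAMS = ("r", "a", "b", "c")


@dataclass
class CorrResult:
    """Pearson correlation with its t-test."""

    rho: float
    t: float
    df: float
    p: float
    n: int
    perfect: bool = False  # |rho| = 1: t infinite, p reported as 0


@dataclass
class CorrelationMatrix:
    """Pairwise correlations among growth rate r and the fit parameters."""

    pairs: dict        # frozenset({p1, p2}) -> CorrResult
    marginals: dict    # environment category -> {param -> list of values}
    n: int

    def get(self, p1: str, p2: str) -> CorrResult:
        if p1 == p2:
            return CorrResult(1.0, math.inf, self.n - 2, 0.0, self.n, perfect=True)
        return self.pairs[frozenset((p1, p2))]


def pearson_t(x, y) -> CorrResult:
    """Sample Pearson correlation with a two-sided t-test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError(f"need n >= 3 for the t-test, got n={n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    # symmetric formula: pearson_t(x, y) and pearson_t(y, x) agree exactly
    rho = float(xc @ yc) / math.sqrt(float(xc @ xc) * float(yc @ yc))
    rho = max(-1.0, min(1.0, rho))
    df = n - 2
    if 1.0 - rho * rho < 1e-15:
        return CorrResult(rho, math.copysign(math.inf, rho), df, 0.0, n, perfect=True)
    t = rho * math.sqrt(df) / math.sqrt(1.0 - rho * rho)
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrResult(rho, float(t), df, float(p), n)


def build_cohort(summaries: list, metadata: dict) -> pd.DataFrame:
    """Join replicate summaries to growth metadata, keeping only
    exponential-phase combinations with a positive growth rate.

    ``metadata`` maps combination_id -> {strain, environment, growth_phase,
    growth_rate}.  Stress-response rows and rows lacking a growth rate are
    excluded with a logged count.
    """
    seen = set()
    rows = []
    n_excluded = 0
    for s in summaries:
        if s.combination_id in seen:
            raise ValueError(f"duplicate combination_id {s.combination_id!r}")
        seen.add(s.combination_id)
        meta = metadata.get(s.combination_id, {})
        env = meta.get("environment")
        if env is not None and env not in ENVIRONMENT_CATEGORIES:
            raise ValueError(f"unknown environment category {env!r}")
        phase = meta.get("growth_phase")
        r = meta.get("growth_rate")
        if phase != "exponential" or r is None or not (r > 0):
            n_excluded += 1
            logger.warning(
                "%s excluded from cohort (phase=%s, r=%s)", s.combination_id, phase, r
            )
            continue
        rows.append(
            {
                "combination_id": s.combination_id,
                "strain": meta.get("strain"),
                "environment": env,
                "r": float(r),
                "mean_a": s.mean_a,
                "se_a": s.se_a,
                "mean_b_norm": s.mean_b_norm,
                "se_b_norm": s.se_b_norm,
                "mean_c": s.mean_c,
                "se_c": s.se_c,
                "n_replicates": s.n_replicates,
            }
        )
    if n_excluded:
        logger.info("cohort filter: %d combinations excluded", n_excluded)
    if not rows:
        raise ValueError("cohort empty after exponential-phase filtering")
    return pd.DataFrame(rows)


_COLUMN_OF = {"r": "r", "a": "mean_a", "b": "mean_b_norm", "c": "mean_c"}


def param_growth_matrix(cohort: pd.DataFrame) -> CorrelationMatrix:
    """All pairwise correlations among {r, a, b, c} over the cohort rows,
    plus per-environment-category marginal value lists."""
    if len(cohort) < 3:
        raise ValueError("need >= 3 cohort rows for correlation")
    pairs = {}
    for i, p1 in enumerate(PARAMS):
        for p2 in PARAMS[i + 1 :]:
            pairs[frozenset((p1, p2))] = pearson_t(
                cohort[_COLUMN_OF[p1]], cohort[_COLUMN_OF[p2]]
            )
    marginals: dict = {}
    if "environment" in cohort.columns:
        for env, sub in cohort.groupby("environment", dropna=True):
            marginals[env] = {
                p: [float(v) for v in sub[_COLUMN_OF[p]]] for p in PARAMS
            }
    return CorrelationMatrix(pairs=pairs, marginals=marginals, n=len(cohort))


# ---------------------------------------------------------------------------
# track correlation (overlapping sliding windows)
# ---------------------------------------------------------------------------


def lag1_autocorr(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    denom = float(v @ v)
    if denom == 0:
        return 0.0
    return float(v[:-1] @ v[1:]) / denom


@dataclass
class TrackCorrelation:
    nominal: CorrResult
    adjusted_p: float
    n_eff: float
    phi: float


def bin_track(
    track: TrackProfile,
    genome_map: GenomeMap,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    circular: bool = True,
) -> SpatialSeries:
    """Length-weighted window means of an interval track on the same sliding
    grid used for expression; bases not covered by any interval carry no
    weight, and all-uncovered windows are interpolated circularly."""
    L = genome_map.length_bp
    dval = np.zeros(L + 1)
    dcov = np.zeros(L + 1)
    for s, e, v in track.intervals:
        if e > L:
            raise ValueError(f"interval ({s},{e}) exceeds genome length {L}")
        dval[s - 1] += v
        dval[e] -= v
        dcov[s - 1] += 1.0
        dcov[e] -= 1.0
    per_base = np.cumsum(dval[:-1])
    cover = np.cumsum(dcov[:-1])

    n_win = L // step_bp
    centers = np.arange(n_win, dtype=float) * step_bp
    half = window_bp / 2.0
    cs_val = np.concatenate([[0.0], np.cumsum(per_base)])
    cs_cov = np.concatenate([[0.0], np.cumsum(cover)])

    lo = ((centers - half) % L).astype(int)
    hi = lo + window_bp
    first_hi = np.minimum(hi, L)
    sums = cs_val[first_hi] - cs_val[lo]
    covs = cs_cov[first_hi] - cs_cov[lo]
    over = np.maximum(hi - L, 0)
    if circular:
        sums = sums + cs_val[over]
        covs = covs + cs_cov[over]
    values = np.full(n_win, np.nan)
    ok = covs > 0
    values[ok] = sums[ok] / covs[ok]
    n_interp = int(n_win - ok.sum())
    if n_interp:
        if not ok.any():
            raise ValueError("track covers no window")
        idx = np.nonzero(ok)[0]
        empty = np.nonzero(~ok)[0]
        values[empty] = np.interp(empty, idx, values[idx], period=n_win)
    return SpatialSeries(
        genome_id=genome_map.genome_id,
        length_bp=L,
        window_bp=window_bp,
        step_bp=step_bp,
        centers=centers,
        values=values,
        circular=circular,
        n_interpolated=n_interp,
        label=track.label,
    )


def windowed_correlation(sa: SpatialSeries, sb: SpatialSeries) -> TrackCorrelation:
    """Correlate two identically binned, Z-scored series window-wise.

    Reports the nominal Pearson t-test p first and an
    autocorrelation-adjusted p using n_eff = n (1 - phi)/(1 + phi) with phi
    the larger lag-1 autocorrelation of the two series.
    """
    if sa.genome_id != sb.genome_id:
        raise ValueError(f"genome mismatch: {sa.genome_id} vs {sb.genome_id}")
    if sa.n != sb.n or sa.window_bp != sb.window_bp or sa.step_bp != sb.step_bp:
        raise ValueError("series binning mismatch")
    nominal = pearson_t(sa.values, sb.values)
    phi = max(lag1_autocorr(sa.values), lag1_autocorr(sb.values))
    phi = min(max(phi, 0.0), 1.0 - 1e-12)
    n_eff = sa.n * (1.0 - phi) / (1.0 + phi)
    n_eff = min(float(sa.n), n_eff)
    if nominal.perfect:
        adj_p = 0.0
    elif n_eff <= 3:
        adj_p = 1.0
    else:
        df = n_eff - 2
        t = nominal.rho * math.sqrt(df) / math.sqrt(1.0 - nominal.rho ** 2)
        adj_p = float(2.0 * stats.t.sf(abs(t), df))
    return TrackCorrelation(nominal=nominal, adjusted_p=adj_p, n_eff=n_eff, phi=phi)


def track_expression_correlation(
    expr_profile: ExpressionProfile,
    track: TrackProfile,
    genome_map: GenomeMap,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> TrackCorrelation:
    """Z-score expression and track signals on the same 100-kb/1-kb sliding
    grid and correlate them window-wise (the GyrA-binding comparison)."""
    if track.genome_id != genome_map.genome_id:
        raise ValueError(
            f"track genome {track.genome_id!r} != map genome {genome_map.genome_id!r}"
        )
    se = zscore_series(bin_profile(expr_profile, genome_map, window_bp, step_bp))
    st = zscore_series(bin_track(track, genome_map, window_bp, step_bp))
    return windowed_correlation(se, st)
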