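"""Least-squares sinusoidal fit at a fixed wavelength.

The model for the expression level at genome position x is

    Exp(x) = a * sin( (x + b) / T * 2 pi ) + c

with amplitude a (log-expression units), phase offset b (bp; the genomic
position of period initiation, defined modulo T) and mean level c.  With T
held fixed at the periodogram peak the model is linear in the
reparameterization A sin(2 pi x / T) + B cos(2 pi x / T) + c, so ordinary
least squares gives the exact global minimum; then a = sqrt(A^2 + B^2) and
b = (T / 2 pi) atan2(B, A) mod T.  The sign ambiguity (-a, b + T/2) is
resolved by always reporting the a >= 0 representative.

Replicate averaging treats the phase as a circular quantity: b_norm values
are averaged as angles 2 pi b_norm, with the standard error derived from
the circular dispersion, so phases straddling the wrap point (e.g. 0.9 and
0.1) average to 0.0, not 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .periodicity import PeriodicityResult
from .spatial_profile import SpatialSeries

logger = logging.getLogger(__name__)

DEGENERATE_REL_TOL = 1e-12


@dataclass
class SineFit:
    """Fitted sinusoid at fixed wavelength T_bp."""

    T_bp: float
    a: float
    b_bp: float
    c: float
    sse: float
    n_points: int
    degenerate: bool = False
    b_over_length: float | None = None  # b_bp / genome length, alternative normalization

    @property
    def b_norm(self) -> float:
        """Phase as a fraction of one wavelength, in [0, 1)."""
        return normalize_phase(self)


@dataclass
class ReplicateSummary:
    """Per-combination parameter means and standard errors over replicates."""

    combination_id: str
    mean_a: float
    se_a: float
    mean_b_norm: float
    se_b_norm: float
    mean_c: float
    se_c: float
    n_replicates: int
    T_bp: float


def fit_sine(series: SpatialSeries, T_bp: float, length_bp: float | None = None) -> SineFit:
    """Exact least-squares fit of a*sin((x+b)/T*2pi)+c at fixed T.

    ``T_bp`` shares units with the series positions (bp unless the series
    was normalized).  Sub-Nyquist wavelengths (T <= 2*step) are rejected.
    """
    if T_bp <= 0:
        raise ValueError("T_bp must be positive")
    x = np.asarray(series.centers, dtype=float)
    y = np.asarray(series.values, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 points to fit three parameters")
    step = series.step
    if T_bp <= 2 * step:
        raise ValueError(f"wavelength {T_bp} at or below the Nyquist limit 2*step={2 * step}")

    w = 2.0 * math.pi * x / T_bp
    design = np.column_stack([np.sin(w), np.cos(w), np.ones(n)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    A, B, c = coef
    resid = y - design @ coef
    sse = float(resid @ resid)
    a = float(math.hypot(A, B))
    sd = float(y.std(ddof=1)) if n > 1 else 0.0
    if a < DEGENERATE_REL_TOL * max(sd, 1.0):
        return SineFit(T_bp, 0.0, 0.0, float(c), sse, n, degenerate=True,
                       b_over_length=_b_over_length(0.0, length_bp, series))
    b_bp = (T_bp / (2.0 * math.pi)) * math.atan2(B, A) % T_bp
    return SineFit(T_bp, a, float(b_bp), float(c), sse, n,
                   b_over_length=_b_over_length(b_bp, length_bp, series))


def _b_over_length(b_bp: float, length_bp: float | None, series: SpatialSeries) -> float | None:
    L = length_bp if length_bp is not None else (series.length_bp or None)
    return float(b_bp / L) if L else None


def fit_at_dominant(series: SpatialSeries, result: PeriodicityResult) -> SineFit:
    """Fit the sinusoid at the wavelength of the periodogram's highest peak,
    T = length / dominant k — the 'approximate curve' of the detection plot."""
    k = result.dominant_k
    T = series.length_bp / k if not series.normalized else 1.0 / k
    return fit_sine(series, T)


def normalize_phase(fit: SineFit) -> float:
    """Phase fraction b/T in [0, 1); comparable across genomes whose period
    count matches even when their lengths differ."""
    if fit.degenerate:
        raise ValueError("phase undefined for a degenerate (flat) fit")
    b = fit.b_bp / fit.T_bp
    return float(b % 1.0)


def circular_mean_norm(values) -> tuple[float, float]:
    """Circular mean and dispersion-based s.d. of phase fractions in [0, 1).

    Returns (mean in [0,1), circular s.d. in the same units, from
    sqrt(-2 ln Rbar) / 2 pi).
    """
    ang = 2.0 * np.pi * np.asarray(values, dtype=float)
    C, S = np.cos(ang).mean(), np.sin(ang).mean()
    R = min(1.0, math.hypot(C, S))
    mean = (math.atan2(S, C) / (2.0 * np.pi)) % 1.0
    if mean >= 1.0:  # a tiny negative angle mod 1.0 rounds to exactly 1.0
        mean = 0.0
    sd = math.sqrt(max(0.0, -2.0 * math.log(R))) / (2.0 * np.pi) if R > 0 else float("inf")
    return mean, sd


def average_replicate_fits(fits: list, combination_id: str) -> ReplicateSummary:
    """Average fitted (a, b_norm, c) over biological replicates.

    Requires >= 2 non-degenerate fits at the same wavelength; degenerate
    members are excluded with a warning.  a and c are averaged
    arithmetically, b_norm circularly; SE = s.d. / sqrt(n).
    """
    usable = [f for f in fits if not f.degenerate]
    n_excluded = len(fits) - len(usable)
    if n_excluded:
        logger.warning("%s: excluded %d degenerate fits", combination_id, n_excluded)
    if len(usable) < 2:
        raise ValueError(
            f"{combination_id}: need >= 2 non-degenerate replicate fits, have {len(usable)}"
        )
    T0 = usable[0].T_bp
    if any(abs(f.T_bp - T0) > 1e-6 * T0 for f in usable):
        raise ValueError(f"{combination_id}: replicate fits have mixed wavelengths")
    n = len(usable)
    a = np.array([f.a for f in usable])
    c = np.array([f.c for f in usable])
    b = np.array([f.b_norm for f in usable])
    mean_b, sd_b = circular_mean_norm(b)
    return ReplicateSummary(
        combination_id=combination_id,
        mean_a=float(a.mean()),
        se_a=float(a.std(ddof=1) / math.sqrt(n)),
        mean_b_norm=mean_b,
        se_b_norm=sd_b / math.sqrt(n),
        mean_c=float(c.mean()),
        se_c=float(c.std(ddof=1) / math.sqrt(n)),
        n_replicates=n,
        T_bp=T0,
    )
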