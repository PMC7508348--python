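"""Sliding-window spatial profiles of gene expression along a circular genome.

A gene's position is its CDS midpoint (configurable to the start codon);
strand is ignored because both strands contribute to one profile.  Windows
of ``window_bp`` (default 100 kb) advance in steps of ``step_bp`` (default
1 kb) and wrap around the origin, so the series is evenly sampled — a
requirement for the Fourier analysis downstream.  Windows containing no
gene midpoint are filled by circular linear interpolation between the
flanking non-empty windows, and the interpolated count is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import ExpressionProfile, GenomeMap

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 100_000
DEFAULT_STEP_BP = 1_000


@dataclass
class SpatialSeries:
    """Windowed values along the chromosome, evenly sampled every step_bp."""

    genome_id: str
    length_bp: int
    window_bp: int
    step_bp: int
    centers: np.ndarray  # window centres, bp (or fraction of genome if normalized)
    values: np.ndarray
    circular: bool = True
    standardized: bool = False
    normalized: bool = False  # centres divided by genome length
    n_interpolated: int = 0
    label: str = ""

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.centers.shape != self.values.shape:
            raise ValueError("centers and values must have equal length")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def step(self) -> float:
        """Sampling interval in the current position units."""
        return float(self.centers[1] - self.centers[0]) if self.n > 1 else float(self.step_bp)

    def is_evenly_sampled(self, rtol: float = 1e-9) -> bool:
        d = np.diff(self.centers)
        return bool(len(d) == 0 or np.allclose(d, d[0], rtol=rtol, atol=1e-12))


def gene_midpoints(genome_map: GenomeMap, position: str = "midpoint") -> dict:
    """Map gene_id -> position on the circle, 1..length_bp.

    The midpoint of a gene spanning ``start..end`` is
    ``start + floor((span - 1) / 2)`` where ``span`` is the circular gene
    length, i.e. half-coordinates round down.  Origin-wrapping genes get the
    circular midpoint (mod length).  ``position='start'`` uses the start
    codon coordinate instead (5' end on the annotated strand).
    """
    L = genome_map.length_bp
    out = {}
    for g in genome_map.genes:
        if position == "start":
            pos = g.start_bp if g.strand == "+" else g.end_bp
        elif position == "midpoint":
            span = g.length_on(L)
            pos = g.start_bp + (span - 1) // 2
            if pos > L:
                pos -= L
        else:
            raise ValueError(f"unknown position convention {position!r}")
        out[g.gene_id] = pos
    return out


def bin_profile(
    profile: ExpressionProfile,
    genome_map: GenomeMap,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    circular: bool = True,
    position: str = "midpoint",
) -> SpatialSeries:
    """Average gene-level log expression in sliding windows along the genome.

    Window ``w`` centred at ``c`` covers the circular arc
    ``[c - window_bp/2, c + window_bp/2)``; its value is the arithmetic mean
    of the expression of genes whose midpoint falls in the arc.  Centres are
    ``0, step_bp, 2*step_bp, ...`` giving ``floor(length_bp / step_bp)``
    windows.
    """
    L = genome_map.length_bp
    if window_bp > L:
        raise ValueError(f"window_bp {window_bp} exceeds genome length {L}")
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    prof, n_dropped = profile.restrict_to(genome_map)
    if prof.n_genes == 0:
        raise ValueError(f"{profile.sample_id}: no genes resolvable on {genome_map.genome_id}")

    mids = gene_midpoints(genome_map, position)
    gene_ids = [g for g in prof.values if g in mids]
    pos = np.array([mids[g] % L for g in gene_ids], dtype=float)
    val = np.array([prof.values[g] for g in gene_ids], dtype=float)
    order = np.argsort(pos, kind="stable")
    pos, val = pos[order], val[order]
    csum = np.concatenate([[0.0], np.cumsum(val)])

    n_win = L // step_bp
    centers = np.arange(n_win, dtype=float) * step_bp
    half = window_bp / 2.0
    lo = (centers - half) % L
    hi = lo + window_bp

    if circular:
        i1 = np.searchsorted(pos, lo, side="left")
        i2 = np.searchsorted(pos, np.minimum(hi, L), side="left")
        sums = csum[i2] - csum[i1]
        counts = (i2 - i1).astype(float)
        over = np.maximum(hi - L, 0.0)
        j = np.searchsorted(pos, over, side="left")
        wrap = over > 0
        sums = sums + np.where(wrap, csum[j], 0.0)
        counts = counts + np.where(wrap, j, 0)
    else:
        a = np.clip(centers - half, 0, L)
        b = np.clip(centers + half, 0, L)
        i1 = np.searchsorted(pos, a, side="left")
        i2 = np.searchsorted(pos, b, side="left")
        sums = csum[i2] - csum[i1]
        counts = (i2 - i1).astype(float)

    values = np.full(n_win, np.nan)
    nonempty = counts > 0
    values[nonempty] = sums[nonempty] / counts[nonempty]
    n_interp = int(n_win - nonempty.sum())
    if n_interp:
        idx = np.nonzero(nonempty)[0]
        empty = np.nonzero(~nonempty)[0]
        if circular:
            values[empty] = np.interp(empty, idx, values[idx], period=n_win)
        else:
            values[empty] = np.interp(empty, idx, values[idx])
        logger.info(
            "%s: interpolated %d of %d empty windows", profile.sample_id, n_interp, n_win
        )

    return SpatialSeries(
        genome_id=genome_map.genome_id,
        length_bp=L,
        window_bp=window_bp,
        step_bp=step_bp,
        centers=centers,
        values=values,
        circular=circular,
        n_interpolated=n_interp,
        label=profile.sample_id,
    )


def normalize_positions(series: SpatialSeries) -> SpatialSeries:
    """Divide window centres by the genome length, mapping them into [0, 1)."""
    if series.normalized:
        raise ValueError("positions already normalized")
    return replace(series, centers=series.centers / series.length_bp, normalized=True)


def zscore_series(series: SpatialSeries) -> SpatialSeries:
    """Standardize to zero mean and unit sample (n-1) standard deviation."""
    v = series.values
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot Z-score a constant series (zero variance)")
    return replace(series, values=(v - v.mean()) / sd, standardized=True)


def series_to_table(series: SpatialSeries):
    """Serialize as a (center, value) table for TSV export."""
    key = "center" if series.normalized else "center_bp"
    return [{key: float(c), "value": float(v)} for c, v in zip(series.centers, series.values)]
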