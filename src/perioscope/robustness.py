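"""Perturbation analyses: essential-gene ablation and GC-content comparison.

Ablation asks whether the detected chromosomal periodicity is driven by a
particular gene set (e.g. the ~300 experimentally essential genes of
E. coli): genes are either removed from the profile (their windows rebinned
without them) or their log-expression is substituted with literal 0.0 —
two different perturbations, since zeros drag window means while removal
does not.  The GC analysis computes a sliding-window GC fraction with the
same binning machinery as the expression profiles, so the two series are
aligned window-for-window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionProfile, GenomeMap
from .periodicity import PeriodicityResult, detect
from .spatial_profile import (
    DEFAULT_STEP_BP,
    DEFAULT_WINDOW_BP,
    SpatialSeries,
    bin_profile,
    zscore_series,
)
from .cohort_stats import TrackCorrelation, windowed_correlation

logger = logging.getLogger(__name__)


@dataclass
class AblationVariant:
    label: str
    mode: str               # 'remove' or 'zero'
    n_genes_affected: int
    result: PeriodicityResult
    dominant_k_changed: bool


@dataclass
class AblationReport:
    baseline: PeriodicityResult
    variants: list


def ablate_genes(profile: ExpressionProfile, gene_ids, mode: str = "remove") -> ExpressionProfile:
    """Return a copy of the profile with the given genes removed or zeroed."""
    if mode not in {"remove", "zero"}:
        raise ValueError(f"mode must be 'remove' or 'zero', got {mode!r}")
    targets = set(gene_ids)
    unknown = targets - profile.values.keys()
    if unknown:
        logger.warning("%d ablation gene ids not in profile", len(unknown))
    hit = targets & profile.values.keys()
    if mode == "remove":
        values = {g: v for g, v in profile.values.items() if g not in hit}
        if not values:
            raise ValueError("ablation would remove every gene")
    else:
        values = {g: (0.0 if g in hit else v) for g, v in profile.values.items()}
    return ExpressionProfile(profile.sample_id, profile.genome_id, values, profile.meta)


def ablation_periodicity(
    profile: ExpressionProfile,
    genome_map: GenomeMap,
    gene_sets: dict,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    modes: tuple = ("remove", "zero"),
    depth: int = 2,
) -> AblationReport:
    """Run period detection on the unmodified profile and on every
    (gene set x mode) variant, flagging changes of the dominant period."""
    baseline = detect(bin_profile(profile, genome_map, window_bp, step_bp), depth)
    variants = []
    for label, ids in gene_sets.items():
        for mode in modes:
            ablated = ablate_genes(profile, ids, mode)
            res = detect(bin_profile(ablated, genome_map, window_bp, step_bp), depth)
            variants.append(
                AblationVariant(
                    label=label,
                    mode=mode,
                    n_genes_affected=len(set(ids) & profile.values.keys()),
                    result=res,
                    dominant_k_changed=res.dominant_k != baseline.dominant_k,
                )
            )
    return AblationReport(baseline=baseline, variants=variants)


def read_gene_set(path) -> list:
    """Gene-set file: one id per line, '#' comments."""
    ids = []
    for ln in open(path):
        ln = ln.split("#", 1)[0].strip()
        if ln:
            ids.append(ln)
    return ids


def gc_profile(
    sequence: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    circular: bool = True,
    genome_id: str = "genome",
    align: str = "center",
) -> SpatialSeries:
    """Sliding-window GC fraction (G+C)/(A+C+G+T); ambiguous bases are
    excluded from the denominator.

    ``align='center'`` (default) places window w at the arc
    [c - w/2, c + w/2) around centre c — the same grid the expression
    binning uses, so the two series compare window-for-window.
    ``align='start'`` uses [c, c + w) instead (plain tiling when
    step = window).
    """
    L = len(sequence)
    if window_bp > L:
        raise ValueError("window larger than sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    cs_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cs_ok = np.concatenate([[0], np.cumsum(is_acgt)])

    n_win = L // step_bp
    centers = np.arange(n_win) * step_bp
    if align == "center":
        half = window_bp // 2
    elif align == "start":
        half = 0
    else:
        raise ValueError(f"unknown align {align!r}")
    lo = (centers - half) % L
    hi = lo + window_bp
    first_hi = np.minimum(hi, L)
    gc = cs_gc[first_hi] - cs_gc[lo]
    ok = cs_ok[first_hi] - cs_ok[lo]
    over = np.maximum(hi - L, 0)
    if circular:
        gc = gc + cs_gc[over]
        ok = ok + cs_ok[over]
    if np.any(ok == 0):
        raise ValueError("window containing only ambiguous bases: GC undefined")
    return SpatialSeries(
        genome_id=genome_id,
        length_bp=L,
        window_bp=window_bp,
        step_bp=step_bp,
        centers=centers.astype(float),
        values=gc / ok,
        circular=circular,
        label="gc",
    )


@dataclass
class GCComparison:
    correlation: TrackCorrelation
    gc_detect: PeriodicityResult
    expr_detect: PeriodicityResult


def gc_periodicity_comparison(gc_series: SpatialSeries, expr_series: SpatialSeries) -> GCComparison:
    """Window-wise correlation of GC content with expression, plus the two
    periodograms side by side (is the expression period a sequence effect?)."""
    corr = windowed_correlation(zscore_series(gc_series), zscore_series(expr_series))
    return GCComparison(
        correlation=corr,
        gc_detect=detect(gc_series),
        expr_detect=detect(expr_series),
    )
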