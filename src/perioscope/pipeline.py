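"""End-to-end orchestration: per-sample detection and cohort correlation
with deterministic, audited reports.

``run_detect`` takes every sample through bin -> detect -> fit-at-dominant
and writes a per-sample report plus the dominant-period tally (the
histogram of period counts across the cohort).  ``run_cohort`` continues
through replicate averaging, exponential-phase filtering and the
parameter/growth-rate correlation matrix.  Per-sample failures are
recorded and skipped rather than fatal — a cohort analysis must tolerate
individual bad samples — and every silent filter (genes dropped, windows
interpolated, samples excluded) is logged as a number.

All report floats are fixed to 10 significant digits, so rerunning an
unchanged configuration reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io_formats import read_expression_table, read_genome_annotation, write_report
from .spatial_profile import (
    DEFAULT_STEP_BP,
    DEFAULT_WINDOW_BP,
    bin_profile,
)
from .periodicity import detect, fishers_g, gene_order_series, periodogram
from .harmonic_fit import average_replicate_fits, fit_at_dominant
from .cohort_stats import build_cohort, param_growth_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression_path: str
    annotation_path: str
    meta_path: str | None = None
    annotation_format: str = "tsv"
    length_bp: int | None = None
    fasta_path: str | None = None
    track_path: str | None = None
    gene_set_path: str | None = None
    window_bp: int = DEFAULT_WINDOW_BP
    step_bp: int = DEFAULT_STEP_BP
    circular: bool = True
    position: str = "midpoint"
    depth: int = 2
    g_mode: str = "windowed"
    phase_filter: str = "exponential"
    out_dir: str = "perioscope_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for p in (self.expression_path, self.annotation_path, self.meta_path,
                  self.fasta_path, self.track_path, self.gene_set_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SampleResult:
    sample_id: str
    series: object
    periodicity: object
    fit: object
    meta: object


@dataclass
class DetectRun:
    samples: list            # SampleResult, successes only
    failures: dict           # sample_id -> error message
    tally: dict              # dominant k -> count


def _sample_report(sr: SampleResult) -> dict:
    res, fit = sr.periodicity, sr.fit
    return {
        "sample_id": sr.sample_id,
        "n": res.n,
        "m": res.m,
        "n_interpolated": res.n_interpolated,
        "ranked": [
            {"k": rp.k, "wavelength_bp": rp.wavelength_bp, "power": rp.power}
            for rp in res.ranked
        ],
        "g_stat": res.g_stat,
        "p_value": res.p_value,
        "g_mode": res.g_mode,
        "fit": {
            "T_bp": fit.T_bp,
            "a": fit.a,
            "b_bp": fit.b_bp,
            "b_norm": fit.b_norm if not fit.degenerate else None,
            "b_over_length": fit.b_over_length,
            "c": fit.c,
            "sse": fit.sse,
            "n_points": fit.n_points,
            "degenerate": fit.degenerate,
        },
    }


def analyse_samples(profiles, genome_map, config: RunConfig) -> DetectRun:
    """bin -> detect -> fit_at_dominant for every profile; failures isolated."""
    samples, failures = [], {}
    for prof in profiles:
        try:
            series = bin_profile(
                prof, genome_map, config.window_bp, config.step_bp,
                config.circular, config.position,
            )
            res = detect(series, depth=config.depth, g_mode="windowed")
            if config.g_mode == "genes":
                gs = gene_order_series(prof, genome_map, config.position)
                g, p = fishers_g(periodogram(gs))
                res.g_stat, res.p_value, res.g_mode = g, p, "genes"
            fit = fit_at_dominant(series, res)
            samples.append(SampleResult(prof.sample_id, series, res, fit, prof.meta))
        except Exception as exc:
            logger.warning("sample %s failed: %s", prof.sample_id, exc)
            failures[prof.sample_id] = str(exc)
    tally = dict(Counter(sr.periodicity.dominant_k for sr in samples))
    return DetectRun(samples=samples, failures=failures, tally=tally)


def _load_inputs(config: RunConfig):
    config.validate_paths()
    genome_map = read_genome_annotation(
        config.annotation_path, config.annotation_format, config.length_bp,
        config.circular,
    )
    profiles = read_expression_table(
        config.expression_path, config.meta_path, genome_map.genome_id
    )
    return genome_map, profiles


def run_detect(config: RunConfig) -> DetectRun:
    """Per-sample detection over an expression table; writes samples.json
    and the dominant-period tally."""
    genome_map, profiles = _load_inputs(config)
    run = analyse_samples(profiles, genome_map, config)
    if not run.samples:
        raise RuntimeError("every sample failed detection")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_report([_sample_report(s) for s in run.samples], out / "samples.json")
    write_report(
        {
            "tally": {str(k): v for k, v in sorted(run.tally.items())},
            "n_samples": len(run.samples),
            "n_failed": len(run.failures),
            "failures": run.failures,
        },
        out / "period_tally.json",
    )
    _write_manifest(config, out)
    return run


def cohort_analysis(detect_run: DetectRun):
    """Replicate averaging + exponential-phase filter + correlation matrix,
    purely in memory; returns (cohort DataFrame, CorrelationMatrix)."""
    groups: dict = {}
    meta_by_comb: dict = {}
    for sr in detect_run.samples:
        comb = sr.meta.replicate_group or sr.sample_id
        groups.setdefault(comb, []).append(sr)
        meta_by_comb.setdefault(comb, sr.meta)
    summaries = []
    for comb, members in sorted(groups.items()):
        fits = [m.fit for m in members]
        try:
            summaries.append(average_replicate_fits(fits, comb))
        except ValueError as exc:
            logger.warning("combination %s skipped: %s", comb, exc)
    metadata = {
        comb: {
            "strain": m.strain,
            "environment": m.environment,
            "growth_phase": m.growth_phase,
            "growth_rate": m.growth_rate,
        }
        for comb, m in meta_by_comb.items()
    }
    cohort = build_cohort(summaries, metadata)
    if len(cohort) < 3:
        raise RuntimeError(f"only {len(cohort)} combinations after filtering; need >= 3")
    return cohort, param_growth_matrix(cohort)


def run_cohort(config: RunConfig, detect_run: DetectRun | None = None):
    """Replicate averaging + exponential-phase cohort + correlation matrix.

    Writes cohort.tsv, matrix.json and a run manifest; returns
    (cohort DataFrame, CorrelationMatrix).
    """
    if detect_run is None:
        genome_map, profiles = _load_inputs(config)
        detect_run = analyse_samples(profiles, genome_map, config)
    cohort, matrix = cohort_analysis(detect_run)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_report(cohort.to_dict(orient="records"), out / "cohort.tsv", "tsv")
    write_report(matrix_report(matrix), out / "matrix.json")
    _write_manifest(config, out)
    return cohort, matrix


def matrix_report(matrix) -> dict:
    cells = {}
    for pair, res in matrix.pairs.items():
        p1, p2 = sorted(pair)
        cells[f"{p1}~{p2}"] = {
            "rho": res.rho,
            "t": None if res.perfect else res.t,
            "df": res.df,
            "p": res.p,
            "n": res.n,
            "perfect": res.perfect,
        }
    return {"n": matrix.n, "cells": cells, "marginals": matrix.marginals}


def _write_manifest(config: RunConfig, out: Path) -> None:
    write_report(
        {
            "tool": "perioscope",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        out / "manifest.json",
    )
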