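"""Synthetic genomes, expression profiles and cohorts with the statistical
structure the analysis assumes.

Expression is generated from the sinusoidal position model

    value(g) = a * sin( (midpoint(g) + b) / T * 2 pi ) + c + N(0, sd^2)

with T = length / k whole periods per circular genome and i.i.d. Gaussian
noise on the log scale (optionally AR(1)-correlated along gene order, for
stress-testing the significance test against autocorrelated nulls).
Cohorts couple the amplitude linearly to a per-combination growth rate,
a = alpha0 + alpha1 * r + N(0, sigma_a^2), with replicates sharing
(a, b, c, r) and differing only in noise.

Defaults emulate an E. coli-scale study: a 4,642 kb circular genome
carrying 4,000 genes of ~1 kb, six periods per genome, growth rates
uniform on 0.2-1.0 per hour, and coupling (alpha0 = 0.1, alpha1 = 0.3,
sigma_a = 0.03).  Every generator is a pure function of its spec,
including the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_formats import ExpressionProfile, GeneRecord, GenomeMap, SampleMeta, write_report

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_BP = 4_642_000
DEFAULT_N_GENES = 4_000
ENV_CYCLE = ("regular", "temperature", "osmotic", "nutritional")


@dataclass
class ProfileSpec:
    """Everything needed to generate one genome + expression profile."""

    length_bp: int = DEFAULT_LENGTH_BP
    n_genes: int = DEFAULT_N_GENES
    placement: str = "uniform"      # or 'poisson'
    k_true: int = 6                 # periods per genome; 0 = flat
    a_true: float = 0.5
    b_true: float = 0.0             # bp, in [0, T)
    c_true: float = 5.0
    noise_sd: float = 0.5
    ar1_rho: float = 0.0            # AR(1) noise correlation along gene order
    mean_gene_bp: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 0 or int(self.k_true) != self.k_true:
            raise ValueError("k_true must be a non-negative integer")
        if self.a_true < 0 or self.noise_sd < 0:
            raise ValueError("a_true and noise_sd must be non-negative")
        if self.placement not in {"uniform", "poisson"}:
            raise ValueError(f"unknown placement {self.placement!r}")

    @property
    def T_bp(self) -> float:
        if self.k_true == 0:
            raise ValueError("flat profile has no wavelength")
        return self.length_bp / self.k_true


@dataclass
class CohortSpec:
    """A strain x condition cohort with amplitude coupled to growth rate."""

    n_combinations: int = 42
    n_replicates: int = 3
    r_range: tuple = (0.2, 1.0)     # per hour
    alpha0: float = 0.1
    alpha1: float = 0.3
    sigma_a: float = 0.03
    b_policy: str = "fixed"         # 'fixed' or 'vary' (uniform per combination)
    c_policy: str = "fixed"         # 'fixed' or 'vary' (N(c_true, 0.2))
    profile: ProfileSpec = field(default_factory=ProfileSpec)
    seed: int = 0

    def __post_init__(self):
        if self.r_range[0] <= 0 or self.r_range[1] <= self.r_range[0]:
            raise ValueError("r_range must be a positive increasing interval")
        if self.n_replicates < 2:
            raise ValueError("need n_replicates >= 2 (replicate SEs require it)")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


def simulate_genome(spec: ProfileSpec) -> GenomeMap:
    """Place non-overlapping genes of mean length ~1 kb on a circular genome.

    'uniform' splits the intergenic slack by a uniform stick-breaking;
    'poisson' uses exponential gaps (rescaled), giving burstier spacing.
    """
    rng = _rng(spec.seed, 0)
    n = spec.n_genes
    if n < 1:
        raise ValueError("need n_genes >= 1")
    lengths = np.clip(
        rng.normal(spec.mean_gene_bp, spec.mean_gene_bp / 5, n).round().astype(int),
        spec.mean_gene_bp // 5, spec.mean_gene_bp * 2,
    )
    total = int(lengths.sum())
    if total >= spec.length_bp:
        raise ValueError(
            f"{n} genes of ~{spec.mean_gene_bp} bp do not fit in {spec.length_bp} bp"
        )
    slack = spec.length_bp - total
    if spec.placement == "uniform":
        cuts = np.sort(rng.uniform(0, slack, n))
        gaps = np.diff(np.concatenate([[0.0], cuts]))
    else:
        raw = rng.exponential(1.0, n)
        gaps = raw / raw.sum() * slack
    gaps = gaps.astype(int)
    start = int(rng.integers(1, spec.length_bp + 1))
    genes = []
    pos = start
    width = len(str(n))
    for i in range(n):
        pos += int(gaps[i])
        s = (pos - 1) % spec.length_bp + 1
        e = (s + int(lengths[i]) - 2) % spec.length_bp + 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"g{i + 1:0{width}d}", s, e, strand))
        pos += int(lengths[i])
    genes.sort(key=lambda g: g.start_bp)
    return GenomeMap(f"synthetic_{spec.length_bp}_{spec.seed}", spec.length_bp, True, genes)


def sine_value(position_bp, a: float, b_bp: float, T_bp: float, c: float):
    """The generating model evaluated at a genome position."""
    return a * np.sin((np.asarray(position_bp, dtype=float) + b_bp) / T_bp * 2 * np.pi) + c


def simulate_profile(
    genome_map: GenomeMap,
    spec: ProfileSpec,
    sample_id: str = "synthetic",
    meta: SampleMeta | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionProfile:
    """Expression values on the sinusoidal position model plus noise."""
    from .spatial_profile import gene_midpoints

    if rng is None:
        rng = _rng(spec.seed, 1)
    mids = gene_midpoints(genome_map)
    ids = [g.gene_id for g in genome_map.genes]
    pos = np.array([mids[g] for g in ids], dtype=float)
    if spec.k_true == 0:
        signal = np.full(len(ids), spec.c_true)
    else:
        signal = sine_value(pos, spec.a_true, spec.b_true, spec.T_bp, spec.c_true)
    if spec.noise_sd > 0:
        eps = rng.standard_normal(len(ids))
        if spec.ar1_rho > 0:
            rho = spec.ar1_rho
            for i in range(1, len(eps)):
                eps[i] = rho * eps[i - 1] + np.sqrt(1 - rho * rho) * eps[i]
        noise = spec.noise_sd * eps
    else:
        noise = 0.0
    values = dict(zip(ids, (signal + noise).tolist()))
    return ExpressionProfile(sample_id, genome_map.genome_id, values, meta or SampleMeta())


def simulate_cohort(
    spec: CohortSpec, genome_map: GenomeMap | None = None
) -> tuple[list, dict]:
    """Generate all replicate profiles of a cohort plus its metadata sidecar.

    Returns (profiles, metadata) where metadata maps sample_id to the
    sidecar fields, including ground-truth columns (prefixed ``true_``)
    for recovery scoring.
    """
    if genome_map is None:
        genome_map = simulate_genome(spec.profile)
    rng = _rng(spec.seed, 2)
    T = spec.profile.T_bp
    profiles: list = []
    metadata: dict = {}
    n_clamped = 0
    for i in range(spec.n_combinations):
        comb = f"comb{i + 1:03d}"
        r = float(rng.uniform(*spec.r_range))
        a = spec.alpha0 + spec.alpha1 * r + rng.normal(0.0, spec.sigma_a)
        if a < 0:
            a = 0.0
            n_clamped += 1
        b = float(rng.uniform(0, T)) if spec.b_policy == "vary" else spec.profile.b_true
        c = float(rng.normal(spec.profile.c_true, 0.2)) if spec.c_policy == "vary" \
            else spec.profile.c_true
        env = ENV_CYCLE[i % len(ENV_CYCLE)]
        pspec = ProfileSpec(
            length_bp=spec.profile.length_bp,
            n_genes=spec.profile.n_genes,
            placement=spec.profile.placement,
            k_true=spec.profile.k_true,
            a_true=float(a),
            b_true=float(b),
            c_true=float(c),
            noise_sd=spec.profile.noise_sd,
            ar1_rho=spec.profile.ar1_rho,
            mean_gene_bp=spec.profile.mean_gene_bp,
            seed=spec.profile.seed,
        )
        for rep in range(1, spec.n_replicates + 1):
            sid = f"{comb}_rep{rep}"
            meta = SampleMeta(
                strain="synthetic",
                condition=comb,
                environment=env,
                growth_phase="exponential",
                growth_rate=r,
                replicate_group=comb,
            )
            profiles.append(simulate_profile(genome_map, pspec, sid, meta, rng=rng))
            metadata[sid] = {
                "strain": "synthetic",
                "condition": comb,
                "environment": env,
                "growth_phase": "exponential",
                "growth_rate": r,
                "replicate_group": comb,
                "true_a": float(a),
                "true_b_norm": float((b / T) % 1.0),
                "true_c": float(c),
                "true_k": spec.profile.k_true,
            }
    if n_clamped > 0.1 * spec.n_combinations:
        logger.warning(
            "amplitude clamped to 0 in %d/%d combinations; coupling may be misconfigured",
            n_clamped, spec.n_combinations,
        )
    return profiles, metadata


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def write_expression_tsv(profiles: list, path: Path) -> Path:
    """Write profiles that share a genome as one gene x sample TSV."""
    ids = sorted(profiles[0].values)
    lines = ["gene_id\t" + "\t".join(p.sample_id for p in profiles)]
    for g in ids:
        lines.append(g + "\t" + "\t".join(f"{p.values[g]:.10g}" for p in profiles))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_annotation_tsv(genome_map: GenomeMap, path: Path) -> Path:
    lines = ["gene_id\tstart\tend\tstrand"]
    for g in genome_map.genes:
        lines.append(f"{g.gene_id}\t{g.start_bp}\t{g.end_bp}\t{g.strand}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write a small deterministic fixture set: a toy genome, one six-period
    profile, one flat (null) profile and one small cohort, with a checksum
    manifest.  Scaled down (500 kb genome, 500 genes, 10 kb windows) so the
    files stay tiny."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = ProfileSpec(
        length_bp=500_000, n_genes=500, k_true=6, a_true=0.5, b_true=20_000.0,
        c_true=5.0, noise_sd=0.25, mean_gene_bp=600, seed=seed,
    )
    genome = simulate_genome(base)
    files: dict = {}
    files["genome.tsv"] = write_annotation_tsv(genome, outdir / "genome.tsv")
    six = simulate_profile(genome, base, "six_period")
    # exactly flat: detection must fail on it, exercising failure isolation
    flat = simulate_profile(
        genome,
        ProfileSpec(**{**base.__dict__, "k_true": 0, "a_true": 0.0, "noise_sd": 0.0}),
        "null_flat",
    )
    files["profiles.tsv"] = write_expression_tsv([six, flat], outdir / "profiles.tsv")
    cspec = CohortSpec(
        n_combinations=6, n_replicates=2,
        profile=ProfileSpec(**{**base.__dict__}), seed=seed,
    )
    cprofiles, cmeta = simulate_cohort(cspec, genome)
    files["cohort.tsv"] = write_expression_tsv(cprofiles, outdir / "cohort.tsv")
    meta_all = dict(cmeta)
    meta_all["six_period"] = {"growth_phase": "exponential", "growth_rate": 0.7,
                              "environment": "regular", "replicate_group": "six"}
    meta_all["null_flat"] = {"growth_phase": "exponential", "growth_rate": 0.7,
                             "environment": "regular", "replicate_group": "null"}
    mpath = outdir / "metadata.yaml"
    mpath.write_text(yaml.safe_dump(meta_all, sort_keys=True))
    files["metadata.yaml"] = mpath
    manifest = {
        "seed": seed,
        "genome_length_bp": genome.length_bp,
        "files": {
            name: {
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                "bytes": p.stat().st_size,
            }
            for name, p in sorted(files.items())
        },
    }
    write_report(manifest, outdir / "manifest.json", "json")
    return {**{k: str(v) for k, v in files.items()}, "manifest.json": str(outdir / "manifest.json")}
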