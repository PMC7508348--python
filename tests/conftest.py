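import numpy as np
import pytest

from perioscope import (
    ExpressionProfile,
    GeneRecord,
    GenomeMap,
    ProfileSpec,
    SampleMeta,
    SpatialSeries,
    simulate_genome,
    simulate_profile,
)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeMap:
    """5 kb circular genome with three genes plus one origin-wrapper."""
    return GenomeMap(
        "toy",
        5_000,
        circular=True,
        genes=[
            GeneRecord("gA", 101, 300, "+"),
            GeneRecord("gB", 1001, 1600, "-"),
            GeneRecord("gC", 4001, 4500, "+"),
            GeneRecord("gW", 4901, 100, "+"),  # wraps the origin
        ],
    )


@pytest.fixture(scope="session")
def small_spec() -> ProfileSpec:
    """Scaled-down study conditions: 500 kb genome, 500 genes, six periods."""
    return ProfileSpec(
        length_bp=500_000, n_genes=500, k_true=6, a_true=0.5,
        b_true=20_000.0, c_true=5.0, noise_sd=0.25, mean_gene_bp=600, seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec) -> GenomeMap:
    return simulate_genome(small_spec)


@pytest.fixture(scope="session")
def small_profile(small_genome, small_spec) -> ExpressionProfile:
    return simulate_profile(small_genome, small_spec, "small6")


def series_from_values(values, length_bp=None, step_bp=1_000) -> SpatialSeries:
    """Wrap a plain vector as an evenly sampled spatial series."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if length_bp is None:
        length_bp = n * step_bp
    return SpatialSeries(
        genome_id="test",
        length_bp=length_bp,
        window_bp=step_bp,
        step_bp=step_bp,
        centers=np.arange(n, dtype=float) * step_bp,
        values=values,
    )
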