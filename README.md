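# perioscope

Chromosomal periodicity analysis of bacterial transcriptomes.

Bacterial gene expression is not spatially uniform along the chromosome:
when log-scale expression is plotted against genome position, *E. coli*
transcriptomes show a repeating wave with a characteristic number of
periods per (circular) genome. perioscope quantifies that pattern and
relates it to population growth. It is aimed at microbial
transcriptomics groups who have gene-level expression tables and genome
annotations and want a reproducible answer to three questions: *is there
a dominant chromosomal period, is it statistically significant, and do
its parameters track the growth rate across strains and conditions?*

## Model

Gene expression at genome position *x* is modelled as a sinusoid of a
fixed wavelength *T*:

```
Exp(x) = a · sin( (x + b) / T · 2π ) + c
```

* **a** — amplitude of the periodic pattern (log-expression units),
* **b** — phase offset: the genomic position where the period initiates
  (bp, defined modulo *T*; reported normalized as b/T),
* **c** — mean transcription level,
* **T** — wavelength, fixed at `length_bp / k` where *k* is the dominant
  integer period count found by the periodogram.

The pipeline is:

1. **Spatial profile** — gene midpoints on the circle, log expression
   averaged in 100-kb sliding windows every 1 kb (`bin_profile`), with
   optional position normalization to [0, 1) and Z-scoring.
2. **Period detection** — Schuster periodogram at integer frequencies
   k = 1..⌊n/2⌋ cycles/genome, ranked by power; significance of the top
   peak by the exact Fisher's g test (`detect`).
3. **Harmonic fit** — exact least-squares estimation of (a, b, c) at the
   fixed dominant wavelength via the linear sin/cos reparameterization
   (`fit_at_dominant`), with circular averaging over biological
   replicates.
4. **Cohort statistics** — replicate means of (a, b/T, c) joined to
   exponential-phase growth rates r; pairwise Pearson correlations with
   two-sided t-tests (`run_cohort`), e.g. the amplitude–growth-rate
   relationship.
5. **Robustness** — gene-set ablation (remove or zero), sliding-window
   GC content, and window-wise correlation with binding tracks such as
   GyrA ChIP signal (with an autocorrelation-adjusted p-value for the
   heavily overlapping windows).
6. **Synthetic data** — generators for genomes, profiles and
   growth-coupled cohorts, so the entire chain is testable offline.

## Worked example

```python
import perioscope as ps

spec = ps.ProfileSpec(seed=1)               # 4,642 kb genome, 4,000 genes,
genome = ps.simulate_genome(spec)           # six periods, a=0.5, noise sd 0.5
profile = ps.simulate_profile(genome, spec, "demo")

series = ps.bin_profile(profile, genome)    # 100-kb windows, 1-kb slide
result = ps.detect(series)
fit = ps.fit_at_dominant(series, result)

print(f"dominant period count k = {result.dominant_k}")
print(f"wavelength = {result.ranked[0].wavelength_bp} bp")
print(f"Fisher's g = {result.g_stat:.4f}, p = {result.p_value:.3g}")
print(f"amplitude a = {fit.a:.4f}, phase b/T = {fit.b_norm:.4f}, mean c = {fit.c:.4f}")
```

prints

```
dominant period count k = 6
wavelength = 773667 bp
Fisher's g = 0.9711, p = 0
amplitude a = 0.4765, phase b/T = 0.9962, mean c = 4.9982
```

The detector recovers the six generating periods (wavelength
4,642,000/6 ≈ 774 kb); g ≈ 0.97 means the top ordinate carries ~97% of
the spectral mass, so the exact tail probability underflows to 0. The
fitted amplitude (0.477) sits slightly below the generating 0.5 because
100-kb window averaging attenuates a 774-kb sine by the factor
sin(πw/T)/(πw/T) ≈ 0.97; the phase estimate 0.9962 is within 0.004 of
the generating phase 0 (circularly).

The same analyses are available from the shell:

```
perioscope --out out simulate cohort
perioscope --out out detect --expression out/expression.tsv \
    --meta out/metadata.yaml --annotation out/genome.tsv \
    --annotation-format tsv --length-bp 4642000
perioscope --out out cohort --expression out/expression.tsv \
    --meta out/metadata.yaml --annotation out/genome.tsv \
    --annotation-format tsv --length-bp 4642000
```

Real data enter through the same readers: GenBank/DDBJ flat files, GFF3
or TSV annotations (`read_genome_annotation`), gene × sample expression
TSVs with a YAML/JSON metadata sidecar (`read_expression_table`),
bedGraph tracks (`read_track`) and FASTA (`read_fasta`).

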