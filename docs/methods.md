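# Methods

This note documents the statistical model behind perioscope, the
conventions and defaults that matter for interpreting its output, and
the design choices made where more than one reasonable convention
exists.

## Coordinates and gene positions

All internal coordinates are 1-based inclusive (the GenBank/DDBJ
convention); bedGraph's 0-based half-open intervals convert at the
boundary via (s, e) → (s+1, e), an exact bijection. A gene spanning the
replication origin of a circular genome is kept as a single record with
`start_bp > end_bp`, so its midpoint is single-valued: the midpoint of a
gene of circular span `L_g` is `start + ⌊(L_g − 1)/2⌋ (mod length)`,
with half-coordinates rounding down. Gene position defaults to the CDS
midpoint — symmetric under strand and stable under partial-length
annotation differences — and can be switched to the start codon
(`position="start"`). Strand is ignored for positioning: both strands
contribute to one spatial profile.

## Spatial profile

Expression is averaged over sliding windows on the circle: window
centres at 0, step, 2·step, … (⌊length/step⌋ windows; defaults 100-kb
window, 1-kb step), window *w* at centre *c* covering the arc
[c − w/2, c + w/2). Windows wrap across the origin, keeping the series
evenly sampled — a requirement of the discrete Fourier transform
downstream. Windows containing no gene midpoint are filled by circular
linear interpolation between flanking non-empty windows rather than
dropped; the interpolated count is recorded on the series and carried
into detection reports. With ~4,000 genes and 100-kb windows the
expected gene count per window is ~85, so interpolation is rare at
study scale and matters only for sparse toy inputs. Z-scoring uses the
sample (n−1) standard deviation; any consistent choice rescales the
periodogram uniformly and cannot change peak ranking.

An open question in the windowing convention is whether a 100-kb/1-kb
"sliding bin" averages gene values directly or averages 1-kb sub-bins.
perioscope averages gene values; the two differ only when gene density
varies strongly within a window.

## Periodogram and ranking

For a series x of length n (mean removed),

    I_k = (1/n) |Σ_t (x_t − x̄) e^{−2πikt/n}|²,  k = 1..⌊n/2⌋.

Candidate periods are the integer Fourier frequencies k in cycles per
genome — the natural grid for a circular chromosome; no zero-padding or
frequency interpolation is applied. A unit-amplitude sinusoid at
frequency k gives I_k = n/4. Ranking is by power descending, ties
broken toward smaller k (the longer wavelength) so results are
deterministic; wavelength is reported as round(length/k) bp, while the
exact value length/k is used for fitting.

## Fisher's g test

g = max(I_k)/Σ I_k over k = 1..m with m = ⌊(n−1)/2⌋: the Nyquist
ordinate of an even-length series has a different null distribution and
is excluded, as is standard. Under Gaussian white noise the exact tail
is

    P(g > g₀) = Σ_{j=1..⌊1/g₀⌋} (−1)^{j−1} C(m, j) (1 − j·g₀)^{m−1}.

The alternating sum is evaluated in floating point with log-domain
terms; when individual terms exceed 10⁴ (the cancellation-prone regime
near g ≈ 1/m at large m) the sum is recomputed in decimal arithmetic at
a precision covering the largest term, so the result is correct to
double precision everywhere. The analytic tail is validated against a
10⁵-draw Monte-Carlo null (m i.i.d. exponential ordinates) in the test
suite.

Caveat: applying the test to the 100-kb-smoothed series inflates
significance relative to the white-noise null, because smoothing
induces strong autocorrelation among the n ≈ 4,642 overlapping windows.
The smoothed series is the default (matching the rest of the pipeline),
but a gene-level mode (`g_mode="genes"`: unsmoothed values in genome
order) is available, and every report records which mode produced its
p-value. Windowed-mode p-values should be read as descriptive rather
than calibrated.

## Harmonic fit

At fixed T the model a·sin((x+b)/T·2π) + c is linear in
(A, B, c) = (a cos φ, a sin φ, c) with regressors sin(2πx/T),
cos(2πx/T), 1, so ordinary least squares returns the global minimum;
then a = √(A²+B²) ≥ 0 and b = (T/2π)·atan2(B, A) mod T. The sign
ambiguity (−a, b+T/2) is always resolved to the a ≥ 0 representative.
Wavelengths at or below the Nyquist limit (T ≤ 2·step) are rejected;
fits with a below 10⁻¹² of the series s.d. are flagged degenerate and
carry no phase. T is held fixed at the periodogram peak rather than
jointly optimized, which keeps the fit convex and matches the two-stage
detect-then-fit procedure.

Because the fit runs on the window-smoothed series, the amplitude is
attenuated by the window transfer factor sinc(πw/T) ≈ 0.972 at
w = 100 kb, T ≈ 774 kb — a ~1.4% downward bias at the default scale,
visible in the recovery statistics and within the ±0.02 tolerance the
tests enforce.

Phase is normalized two ways: b/T (phase fraction, the primary
normalization, comparable across genomes when the period count matches)
and b/length (also emitted, since genome lengths differ between
strains). Replicate averaging treats b/T as a circular quantity: means
via the resultant of angles 2π·b/T, dispersion via √(−2 ln R̄)/2π, so
phases 0.9 and 0.1 average to 0.0. Amplitude and mean level average
arithmetically; SE = s.d./√n with n ≥ 2 non-degenerate fits required.

## Cohort statistics

Only exponential-phase samples carry interpretable growth rates, so the
cohort table filters to growth_phase = exponential with r > 0;
stress-response samples are excluded with a logged count. Correlations
are computed on per-combination replicate means (one point per strain ×
condition combination), not per-sample values, and use the sample
Pearson coefficient with t = ρ√(n−2)/√(1−ρ²) on n−2 df, two-sided.
Environment labels form a closed vocabulary {regular, temperature,
osmotic, nutritional}; unknown labels are rejected rather than coerced.
Replicate averaging requires a common wavelength: when a combination's
replicates disagree on the dominant period (which happens at low
signal-to-noise), the combination is excluded with a logged warning
rather than averaged across incompatible fits.

Window-wise track correlations (expression vs a binding track on the
same 100-kb/1-kb grid) are reported with two p-values: the nominal
t-test p first, and an adjusted p using the effective sample size
n_eff = n(1−φ)/(1+φ), φ being the larger lag-1 autocorrelation of the
two series. With 100-fold window overlap, φ ≈ 0.999 and n_eff collapses
from ~4,600 to a handful — the adjusted p is the honest one; the
nominal one is kept for comparability with the windowed convention.

## Robustness analyses

Gene ablation has two distinct modes: *remove* (genes absent, windows
rebinned without them) and *zero* (log-expression literally set to 0.0,
which drags window means toward zero). Both are run for every gene set
and compared to the unmodified baseline by dominant period count.
GC content is computed with the same window machinery ((G+C)/(A+C+G+T)
per window, ambiguous bases excluded from the denominator; a window of
only ambiguous bases is an error). GC windows are centre-aligned by
default so they compare window-for-window with expression; a
start-aligned variant (`align="start"`) gives plain tiling when
step = window.

## Synthetic data

The generator emulates an E. coli-scale study: a circular 4,642-kb
genome carrying 4,000 non-overlapping genes of ~1 kb (uniform
stick-breaking spacing by default, exponential gaps as an alternative),
expression from the sinusoidal position model with i.i.d. Gaussian
noise on the log scale, and cohorts of 42 strain × condition
combinations whose amplitude is linearly coupled to a growth rate drawn
uniformly from 0.2–1.0 h⁻¹: a = α₀ + α₁·r + N(0, σ_a²), clamped at 0
(the clamp rate is surfaced, with a warning above 10%). Defaults
α₀ = 0.1, α₁ = 0.3, σ_a = 0.03 and per-gene noise sd 0.5 are generator
conventions chosen to give cohort detection power near 0.9 at
42 combinations × 3 replicates — they are properties of the synthetic
study design, not measured biology. Replicates share (a, b, c, r) and
differ only in noise. An AR(1) option correlates noise along gene order
for stress-testing the significance test against autocorrelated nulls.

What the generator does *not* emulate: microarray probe effects and
hybridization noise, replication-associated copy-number gradients,
macrodomain-structured (non-sinusoidal) spatial patterns, and
between-sample normalization artefacts. Passing recovery tests
therefore demonstrates the estimators are correct under the stated
model, not that real transcriptomes follow a pure sinusoid.

Every generator is a pure function of its spec including the seed;
fixture sets are written with a SHA-256 manifest and are byte-identical
across runs.

## Problem sizes in tests and the acceptance script

Unit and pipeline tests run on scaled-down instances (500-kb genomes,
500 genes, 10-kb windows) that preserve the windows-per-period ratio.
Statistical validation uses the study-scale conditions: 100 profiles for
period/parameter recovery, 100 coupled + 200 null cohorts in the test
suite; the acceptance script summarizes the same quantities with 100
profiles, 20 coupled cohorts, 50 null cohorts and 20 ablation seeds.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted tolerances.

## Known limitations

* Single-replicon genomes only; plasmids and secondary chromosomes are
  rejected at the FASTA reader.
* The windowed Fisher's g p-value is anticonservative (see above); use
  the gene-level mode for calibrated significance.
* No multi-harmonic fitting: one sinusoid at the dominant wavelength.
  Profiles with two comparable spectral peaks are summarized by the
  ranked list, not a joint model.
* Missing expression values are rejected, not imputed; upstream
  filtering/normalization is assumed done.
* Local (chromosome-arm-specific) periodicity and wavelet-type analyses
  are out of scope.
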