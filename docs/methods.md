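# Methods

## Model and procedure

The pipeline infers relative copy number from the total fluorescence of
methylation-array probes.  The core assumption is multiplicative: a probe's
combined (methylated + unmethylated) intensity is proportional to the local
DNA quantity, scaled by a probe-specific brightness and a sample-specific
factor (array batch, DNA input).  Everything downstream follows from letting
the control panel estimate the probe × sample expectation under diploidy.

**Normalization.**  Each query sample's combined intensities are regressed on
the control samples' intensities by unconstrained least squares *without
intercept on the linear intensity scale*: the fitted combination
`Σ_c β_c C_{p,c}` acts as a synthetic diploid reference tailored to the query
array, and `r_p = log2(I_p / fitted_p)` is the per-probe log2 copy-number
ratio, median-centred per sample.  Fitting on the intensity scale (rather
than on log-intensities) is deliberate: copy number and sample scale act
multiplicatively on intensity, so a sample-wide rescaling is absorbed
*exactly* into β and the ratios are invariant to it (the test suite checks
this to 1e-6); a no-intercept fit on log intensities cannot absorb such a
shift, because the constant vector is not in the span of the control
log-intensity columns.  Collinear control columns are detected by pivoted QR
and dropped with a warning; fewer than two independent controls is fatal.
Median-centring (not mean) is used so a real CNV occupying a minority of the
genome does not bias the baseline.

**Probe filtering.**  Probes are excluded identically for all samples when
(a) their median combined intensity across controls falls below
`min_combined` (default 100 fluorescence units — dim probes contribute mostly
ratio noise) or (b) they are missing in any sample.  Missing measurements are
NaN, never zero: a zero would be indistinguishable from a homozygous
deletion.

**Binning.**  The unit of testing is a fixed genomic bin holding at least
`min_probes = 15` CpG probes and spanning 50–150 kb.  Construction is a
greedy left-to-right merge of 50-kb tiles anchored at position 1 of each
chromosome: tiles accumulate until the probe count reaches 15 (emit), or the
span would pass 150 kb first (flush, emit nothing).  A run reaching 15 probes
exactly at 150 kb is emitted.  This is the simplest deterministic rule that
satisfies both the probe minimum and the size range, its outputs are
exhaustively checkable by brute-force enumeration, and — because it depends
only on the manifest and the probe mask — the bin set is constant across
samples and cohorts.  Grid anchoring at 1 makes bin boundaries fall on
…000001/…00000 coordinates.  Bin values are the arithmetic mean of member
probe ratios (the t-test below models means; the mean keeps the estimator
linear), with a median option in the aggregation config.

**Inference.**  Bins are compared between exactly two groups with the
pooled-variance Student t-test, `df = n_A + n_B − 2`, two-sided p from the t
distribution.  Welch's correction is available behind a config flag but is
not the default, since the equal-variance form is the conventional choice for
this design.  Degenerate zero-variance bins are defined explicitly: equal
means → t = 0, p = 1; unequal means → p = 0, flagged.  Bonferroni adjustment
multiplies by the number of bins *actually tested* (after post-hoc bin
drops), not the nominal manifest bin count — family-wise validity requires
the realized family size.  Significance is adjusted p < α, default α = 0.05.

**Regions and calls.**  Maximal runs of significant bins that are consecutive
in the bin set (no intervening emitted bin), on one chromosome and with
same-sign delta merge into a region.  A region reports the *minimum* adjusted
p and the *mean* delta of its members — the most conservative single-row
summary of a multi-bin event.  Gain/loss calling uses a symmetric threshold
θ = 0.2 on the region's log2 ratio: gain above +θ, loss below −θ, neutral in
between.  (The threshold is conventional for array-based CNV work; note that
published per-bin deltas of ±0.17 magnitude fall below it and are reported as
significant-but-neutral.)  Gene annotation intersects regions with BED
intervals converted to the pipeline's 1-based inclusive convention; any
overlap ≥ 1 bp counts, names are deduplicated in annotation order.

**Coordinates.**  Internally everything is 1-based inclusive with
length = end − start + 1; BED input/output converts at the boundary.
Chromosome names are taken verbatim by default (a `harmonize_chroms` flag
adds missing `chr` prefixes on both manifest and annotation).

## Synthetic cohorts

The simulator emulates the statistical structure the estimation stage relies
on, not array chemistry.  Combined intensity is
`I_{p,s} = B_p · γ_s · (c_eff/2) · 2^ε` with

| parameter | default | meaning |
|---|---|---|
| `baseline_log_mean` | 7.6 (ln scale, ≈ 2,000 units) | median probe brightness |
| `baseline_log_sd` | 0.7 (ln scale) | probe-to-probe brightness spread |
| `sample_scale_sd` | 0.1 (ln scale) | per-sample array/input scale variation |
| `noise_sd` | 0.2 (log2 scale) | per-probe-per-sample multiplicative noise |
| `control_count` | 20 | diploid reference panel size |
| `meth_fraction_alpha/beta` | 2 / 2 | Beta split of I into the two channels |

Noise is multiplicative log-normal because fluorescence intensities are
positive and right-skewed and the pipeline operates on log2 values.  Real
arrays are not noise-characterized in a way we can import, so `noise_sd` is a
free parameter; the validation suite states its choices explicitly (0.2 for
null calibration, 0.1 for recovery experiments).  Implanted CNVs have integer
copy number `c` and cell fraction φ (tissue purity), giving effective copy
number `2(1 + φ(c/2 − 1))` in targeted query samples; controls are diploid
everywhere.  φ lets effects be attenuated to the ±0.17 magnitudes typical of
published bulk-tissue comparisons, far from the pure-clone −1/+0.585.  All
draws flow from a single seeded generator, so cohorts are byte-reproducible.

What the simulator deliberately omits — Infinium I/II probe-type chemistry,
GC waves, batch effects, realistic EPIC probe spacing — bounds what passing
tests demonstrate: they validate the statistical chain (normalization,
binning, error control, recovery) under the stated noise model, not
robustness to array artifacts.

## Validation scales

The validation suite and `scripts/acceptance.py` use problem sizes chosen to
give stable Monte-Carlo estimates while staying desk-sized: null calibration
uses 1,000 replicates of a ~200-bin chromosome (10 Mb at probe density
4×10⁻⁴) with 8 + 8 query samples and 20 controls at noise 0.2 — about 4,000
t-tests per second end to end; recovery uses 100 replicates at noise 0.1 with
three implanted 200-kb events (expected ratios −1.0, −0.165, +0.177); bin
geometry is exercised over 50 manifests spanning densities 1.5–6×10⁻⁴ (from
"most tiles must merge" to "every tile is a bin").  The empirical family-wise
error rate is compared against α allowing two binomial standard errors
(±0.014 at 1,000 replicates).

## Numerical choices and edge cases

- `log2(I + 1)` is used where raw log-intensities are reported (defined at
  I = 0, negligible at realistic intensities); the ratio itself uses no
  pseudocount so that scale invariance is exact, and probes with non-positive
  query or fitted signal become NaN with a warning (the default probe filter
  removes them first).
- Least squares is solved by `numpy.linalg.lstsq` after pivoted-QR rank
  detection; per-sample fits and the batched multi-sample path are
  numerically identical and are cross-checked against direct normal-equation
  solutions to 1e-8 in the tests.
- Bin aggregation uses `nanmean` over member probes; a bin losing all its
  probes post-hoc is dropped with a logged count and shrinks the Bonferroni
  family accordingly.
- Ties in bin construction: reaching `min_probes` exactly when the span
  reaches `max_size` emits the bin.
- Report TSVs write floats via `repr` and are re-read with round-trip float
  parsing, so write → read is exactly lossless.

## Known limitations

- No segmentation (CBS or similar): inference is fixed-bin by design, which
  trades resolution at CNV boundaries for a constant, comparable unit across
  samples.
- The two-group t-test assumes approximately equal variances and
  exchangeable samples; no covariates, pairing or batch adjustment.
- Bonferroni is conservative under correlated adjacent bins; power at
  |Δ| ≈ 0.17 with n = 8 vs 8 is near the detection floor (the recovery suite
  documents estimation accuracy there, not detection).
- Gain/loss calls depend on the conventional θ = 0.2 threshold, whose mapping
  to integer copy number is confounded by cell fraction.
- IDAT files are not parsed; the canonical input is a tabular intensity file
  (an external converter can produce it).
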