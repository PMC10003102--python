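# Methods

## Stereological volume estimation

Rounded organelles are modelled as spheres observed as circular profiles in
EM thin sections. The forward process: a slab of thickness *t* at a uniform
random depth cuts a sphere of radius *R* when the slab centre lies within
*R + t/2* of the sphere centre, so the probability that a given organelle is
observed at all is proportional to *2R + t* (size-biased sampling). Within
the slab the largest cut circle dominates the projection, giving profile
radius √(R² − d²) with d = max(0, |z| − t/2).

For uniformly random diametric offsets at *t = 0* the expected apparent
diameter is (π/4)·D, hence the per-profile correction D₀ = 4d/π applied
after the sphericity filter (long:short axis ratio strictly < 1.3; the mean
of the two axes is the apparent diameter, a geometric-mean alternative is
configurable). The correction is stated for modal diameters; because it is
linear, correcting every profile and correcting only the mode by the same
factor coincide, and the `correction: per_object | modal_only` switch is
therefore presentational. Two caveats the package makes explicit rather
than hiding:

- **Finite slab thickness** biases the corrected mean upward (every offset
  within ±t/2 of the equator projects the full diameter). The Monte Carlo
  oracle shows the bias is positive and monotone in *t* (tested at
  t ∈ {0, 30, 60, 120} nm); at the 55–65 nm sections typical of EM and
  ~300 nm organelles it is a few percent. No thickness deconvolution is
  attempted.
- **Jensen bias of the cubic**: the mean of per-profile volumes exceeds the
  volume of the mean corrected diameter by E[r³]/E[r]³ = (96/π²)/8 ≈ 1.216
  at t = 0. Population volume recovery is therefore assessed on the volume
  of the recovered mean diameter; the per-object volume distribution (the
  quantity histogrammed in practice) is reported as-is.

Rod-shaped organelles cannot be measured in thin sections; lengths are
taken from confocal images and converted by the cylinder model
π(d/2)²L with d = 150 nm. Units are fixed package-wide: EM lengths nm,
confocal lengths µm, volumes aL (1 aL = 10⁶ nm³). No Wicksell/Saltykov
unfolding of the full size distribution is performed; only the modal/mean
correction above is applied, so distribution *shape* retains the sectioning
spread — a known limitation.

## Luminal pH inference

Single-protonation model f(pH) = 1/(1 + 10^{n(pKa − pH)}). The measured
rest/max ratio equals f(pH)/f(pH_ref) because the NH₄Cl clamp is assumed to
bring the lumen to pH_ref. Defaults pKa = 6.0, n = 1.0, pH_ref = 7.4 are
canonical eGFP protonation behaviour; they are configuration, not data, and
are echoed into every output. The admissible ratio interval is the open
(0, 1/f(pH_ref)); ratios outside it (noise, mis-segmented organelles) are
QC-flagged and excluded from summaries, never clamped. From traces, F_rest
is the mean of the final 10 s before application and F_max the maximum of a
3-sample boxcar-smoothed post-application segment (robust to single-sample
spikes). Equilibration kinetics of the clamp are not modelled.

## Exocytosis kinetics

Stimulus onset: first time the Ca²⁺-indicator ratio exceeds baseline mean +
5·sd for 3 consecutive samples, with the baseline taken from the first 20 %
of the trace (or an explicit window). Because the true crossing lies
between two samples, the reported onset is the midpoint of that sampling
interval — an unbiased convention at the cost of half-sample granularity.
Delay is the first post-onset event minus onset (a time-to-5 %-of-events
alternative is configurable); events before onset are excluded with a
warning, since spontaneous fusion occurs. Maximal rate is the maximum over
all placements of a 1 s window (width configurable and recorded); the
implementation evaluates windows anchored at event times, which provably
attains the global maximum, and is tested against a brute-force oracle.
Fraction released uses the per-cell labelled-WPB count supplied as input.

## String morphometry

String length is the arc length of the traced polyline (chord-length
switch available); strings shorter than 20 µm are excluded, a string of
exactly 20 µm is kept. Platelet density is platelets/µm per string averaged
over strings (default, matching per-string plots) or pooled
(total/total). Group statistics: one-way ANOVA for lengths, Welch *t* for
two-group density contrasts, whisker summaries with type-7 quantiles and
1.5·IQR whiskers clipped to the data. The optional image pathway thresholds
(Otsu), skeletonizes, and takes each component's longest path found with
8-connected steps weighted 1/√2; the reported length measures that path as
a polyline subsampled every 5 pixels, because raw step sums overestimate
digitized smooth curves by ~6–8 % (staircase bias) while the subsampled
polyline stays within the pathway's 5 % tolerance for the curvatures the
generator produces.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure of the measurements:
size-biased slab sectioning with multiplicative log-normal axis jitter
(exercising the sphericity filter), log-normal rod and string length
populations, Hill-model fluorescence with relative Gaussian noise and a
step trace at the clamp time, per-cell latency (normal, truncated at 0)
followed by homogeneous-Poisson fusion arrivals truncated at the releasable
pool, saturating-exponential Ca²⁺ rise (τ = 0.3 s) beginning exactly at the
stimulus, persistent-random-walk strings (heading increments
N(0, 0.15 rad) per 0.5 µm step) with Poisson platelets along arc length.

They deliberately do **not** emulate: optics (PSF, pixel noise, photo-
bleaching), EM texture, segmentation errors, rod end-caps or partial-volume
effects, Ca²⁺ dose–response shape, or string tension/breakage under flow.
Passing recovery tests therefore demonstrates correctness of the estimators
given faithful 2D measurements, not robustness to image-analysis error.

Default study-scale conditions: 60 nm section thickness (midpoint of
ultrathin sectioning), 300 nm spheres, 150 nm rod diameter, pH populations
N(5.41, 0.2) and N(5.73, 0.2) with 1 % fluorescence noise at n = 135 / 92,
11 cells with ~100 labelled WPBs, 2.6 ± 0.5 s latency, 4 events/s, 20 %
releasable fraction, string means 208 µm and 58.43 µm (log-sd 0.4) with 0.2
platelets/µm. Traces default to 45 s at a 10 s onset so the baseline window
ends before the stimulus.

All randomness flows from one integer seed through named substreams (one
per generator, keyed by a CRC of the generator name), so adding a generator
never perturbs another's draws and identical spec + seed reproduce tables
byte-identically.

## Numerical and I/O choices

- CSV, UTF-8, '.' decimal; units in column names (`_nm`, `_um`, `_s`);
  floats parsed with round-trip precision so write∘read is byte-stable.
- sem reported as 0 with an explicit n = 1 flag for singleton groups;
  empty inputs yield empty outputs with zero counts where the operation is
  a filter, and explicit errors where an estimate would be undefined.
- Welch (unequal-variance) *t*-tests throughout; ANOVA is the classical
  equal-variance one-way form.
- Every run writes `manifest.json` (input SHA-256 digests, config snapshot,
  package version, seed, timestamp); deterministic stages reproduce
  byte-identically from identical manifest inputs.

## Known limitations

- The sphere model is only as good as the sphericity filter; strongly
  prolate organelles that slip under the 1.3 ratio bias diameters upward.
- No unfolding of the apparent-size *distribution* (see above); summary
  statistics of corrected per-object values inherit sectioning spread.
- pH inference is single-protonation; sensors with cooperative protonation
  need the Hill coefficient calibrated, and chloride/quenching effects are
  out of scope.
- The image pathway resolves branched skeletons to the longest path, which
  undercounts total length when strings genuinely branch or cross.
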