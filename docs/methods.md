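# Methods notes

This note records the scientific and numerical choices behind `avakit`:
what each stage computes, which parameters matter, what the synthetic
cohorts do and do not emulate, and where the method's known limitations
lie.

## Avalanche extraction

ROI time courses are z-scored **per ROI over the full recording** (all
contiguous segments concatenated), not per segment: the threshold should
mean the same thing everywhere in a recording, and per-segment scaling
would make short segments noisier than long ones. A sample is *active*
when |z| exceeds the threshold; positive and negative excursions count
equally. Zero-variance rows are an error (the offending ROI is named)
rather than silently producing all-zero rows.

Recordings may contain discontinuities (e.g. upstream artifact excision).
Segment boundaries are carried explicitly, and three rules follow from
them:

* binning restarts at each boundary, and a trailing partial bin within a
  segment is dropped, never padded — padding would fabricate silence;
* no avalanche spans a boundary;
* runs that touch a segment edge are discarded as incomplete: their true
  onset or offset was not observed, and keeping them would bias both the
  branching ratio and the transition matrix toward truncated dynamics.

The minimal-duration filter applies **after** binning, in bins, because
that is the unit in which a duration criterion is meaningful for binned
avalanche analysis. Bin intervals are 0-based and half-open throughout.

## Branching ratio and bin choice

Per avalanche, σᵢ is the geometric mean over successive bin pairs of the
descendant/ancestor event-count ratio; it telescopes algebraically to
`(n_last/n_first)^(1/(N−1))` and the implementation uses that closed form
(the bin-by-bin product is verified against it in tests to 1e-12). σ is
the geometric mean of σᵢ over all avalanches of at least two bins;
single-bin avalanches carry no ancestor–descendant pair and are excluded.
`select_bin_size` picks the candidate bin whose σ is closest to 1 (ties
toward the smaller bin), the usual operating point for critical dynamics.

**Estimator limitation.** Because σᵢ depends only on the first and last
bins of a terminated avalanche, and an avalanche by definition ends just
before a silent bin, the last bin is almost always small. A supercritical
cascade *conditioned on having terminated* is distributionally equivalent
to a subcritical one, so this estimator saturates near 1 from below for
strongly supercritical dynamics; it cleanly separates subcritical from
critical regimes (σ < 1 vs σ ≈ 1) but should not be read as an unbiased
estimate of the true branching parameter above 1. The test suite asserts
the monotone ordering σ(ρ=0.5) < σ(ρ=1) and the critical calibration
σ(ρ=1) ∈ [0.9, 1.1], which is the regime the workflow actually relies on.

## Avalanche transition matrix

Within one avalanche, entry (i, j) is the conditional frequency of j
being active δ bins after i, normalized by the number of bins in which i
was an ancestor; the per-avalanche matrices are averaged element-wise
across avalanches. δ defaults to 1 bin (4 ms at 250 Hz and bin size 1).
Whether per-avalanche matrices should be ancestor-normalized conditionals
or binary occurrence indicators is genuinely ambiguous in the avalanche
literature; the conditional reading is the default and an indicator mode
(`mode="binary"`) is kept behind a flag. Rows of ROIs that never served
as ancestors are zero, not missing, so the feature space stays fixed
across subjects. The diagonal is retained in the matrix; feature
vectorization excludes it.

## Imaginary coherence

Cross-spectra use Welch segmentation (10 s windows, 50% overlap) with a
DPSS taper family. The time-(half-)bandwidth product NW defaults to 4
with 2·NW−1 = 7 tapers — the standard variance/bandwidth trade-off for a
10 s window; at 250 Hz that gives a native grid spacing of 0.1 Hz and no
zero-padding is applied (the stated resolution is the native one).
Windows never straddle segment boundaries; each window is mean-detrended
before tapering. The convention is S_xy = ⟨X(f)·Y*(f)⟩; the sign of
Im(S_xy) therefore encodes lead/lag direction, and since that orientation
is arbitrary for classification purposes, the **absolute value** of
ImCoh is taken per frequency before unweighted band averaging (a signed
variant sits behind `signed=True` and is antisymmetric). Band averaging
is an unweighted mean over grid frequencies because no weighting is
better motivated. Identical signals give exactly 0; a vanishing
autospectrum at a band frequency raises an error naming the ROI and
frequency.

## Classification

Edge features are all n(n−1) ordered off-diagonal entries for ATMs and
the n(n−1)/2 upper-triangle entries for ImCoh, in deterministic row-major
order. Evaluation is a stratified 80/20 shuffle split repeated 50 times;
stratification is used because with ~30 subjects per group an
unstratified 20% test set can end up single-class. Within each training
partition a 5-fold grid search (accuracy-scored) selects kernel ∈
{linear, RBF} and C ∈ {1e-2 … 1e2} (a log ladder; the method names C but
no values, and this range brackets the margin scales that matter after
standardization). Features are standardized with training-set statistics
only — otherwise edge coefficients are not comparable across edges —
and constant training columns keep scale 1. All metrics are recomputable
from the stored confusion counts; ROC curves use the SVM decision
function. Everything is deterministic given the seed.

Importance is defined only for linear-kernel splits (RBF machines have no
per-feature coefficients): per edge, the median over linear splits of
|coefficient|; per node, the arithmetic mean over incident edges (both
directions for ATMs). If the grid never selects the linear kernel the
call fails with advice to restrict the kernel grid.

Threshold/min-duration optimization runs the full pipeline over the grid
(thresholds 1.2–3.0, durations 2–8 bins) and ranks pairs by mean
accuracy, ties toward the higher threshold then the shorter duration. By
default pairs are ranked by the *inner*-CV accuracy ("nested" mode),
because ranking by held-out accuracy re-uses the test subjects for a
selection decision and is optimistic; the "test" mode is available
explicitly, and all pairs' scores are returned for audit.

## Window-length analysis

For each window length, a contiguous window is placed uniformly at random
per subject (independently across subjects and placements), ATMs are
computed from that window only, and the full classification runs; per
cross-validation split the median accuracy over placements is recorded.
Binarization uses z-scores from the full recording so that the threshold
does not drift with window length, and the avalanche parameters are held
fixed across lengths — re-optimizing per length would confound the
time-scale effect. Windows are contiguous in recording time; original
segment boundaries inside a window are still respected by the detector,
and avalanches cut by the window edge are dropped like any other
incomplete run.

## Synthetic cohorts

The generator produces the *kind* of structure the pipeline measures: a
directed propagation graph (random topology at density 0.5, uniform
weights rescaled so every row sums to the branching parameter ρ) drives a
discrete process in which active ROIs recruit their targets by noisy-OR,
silent networks reseed spontaneously, and a 1-bin refractory period
prevents frozen always-on states. Group B's graph rewires a fraction
`effect_size` of group A's edges to empty slots, preserving row sums —
the group difference lives purely in propagation topology, not in
spectra, amplitudes, or rates.

Defaults are the cohort conditions used throughout the tests: 68 ROIs at
250 Hz, 300 s per subject, ~30 subjects per group, ρ = 1. The drive rate
(0.008 per ROI per silent bin) was calibrated once so that the
geometric-mean branching estimator reads σ ≈ 1.00 at ρ = 1 and bin 1 —
the operating point the avalanche literature reports for resting-state
source data — which requires avalanches to start from one-to-few seeds
(heavier seeding drags the estimator below 1, single seeding floors it
above 1).

Rendering a raster to a continuous series places signed pulses (random
sign per activation) on a Gaussian noise floor. Active samples take the
exact value ±A with A calibrated per ROI so that, after the z-scoring the
analysis applies, pulse samples land at `burst_amplitude_z` (default 4.0)
z-units; this requires `z² · active_fraction < 1` and errors otherwise.
Because the pulse value is exact, any threshold below the pulse height
recovers the simulated raster deterministically, and false positives are
controlled by the noise floor alone (≈ 10⁻⁴ per sample at threshold 3).
Note that z-scoring imposes a variance budget — one cannot independently
choose pulse z-height, relative noise level, and activity rate — which
is why the pulse replaces rather than adds to the noise at active
samples.

What the cohorts do **not** emulate: 1/f background spectra, oscillatory
rhythms, volume-conduction mixing, inter-subject anatomical variability,
non-stationary arousal drift, or realistic avalanche waveform shapes.
Passing the cohort-level tests therefore demonstrates that the pipeline
recovers propagation structure it is pointed at, not that any particular
clinical accuracy is attainable on real recordings.

## Pipeline defaults and numerics

* Band presets: broadband 3–40 Hz, narrowband 3–14 Hz; custom pairs
  accepted. Source-space filtering uses a zero-phase forward–backward
  Butterworth band-pass of order 4 (an uncontroversial default where no
  specific design is prescribed), applied per segment.
* Binarization threshold 3.0 z, minimal avalanche duration 2 bins, δ = 1
  bin, bin size 1 by default.
* An optional uniform-duration truncation (`truncate_s`) equalizes
  recording lengths before feature extraction, and is logged per subject.
* Reports carry a reproducibility block: resolved config, its SHA-256
  hash (first 12 hex digits), seed, and package versions.
* Problem sizes in the validation suite (e.g. 30+30 subjects at 300 s for
  effect-recovery, 12+12 at 310 s with 10 window placements for the
  window-length trend, 500+ avalanches for the σ calibration) were chosen
  as the smallest cohorts at which the respective effects are stable
  across seeds.

## Known limitations

* The σ estimator's supercritical saturation (above).
* ATM entries for weak or absent edges pick up a co-activation background
  (two simultaneously active ancestors each get credited with the other's
  descendants), which bounds ground-truth rank recovery around 0.87 at
  the default density even in the noise-free limit.
* Selecting avalanche parameters by classification accuracy — even inner-
  CV accuracy — is a model-selection step; reported accuracies after such
  a search are mildly optimistic unless validated on untouched data.
* The CLI ingests ROI-level text matrices only; raw-EEG formats,
  preprocessing, and source reconstruction are out of scope by design.
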