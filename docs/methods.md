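# Methods

`ierp` implements a within-session analysis of evoked intracranial EEG
(iEEG) responses to two levels of musical structure — individual note
onsets and phrase boundaries — and the cross-session integration of its
results. This note documents the model assumptions, the parameters that
matter, what the synthetic data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## The analysis model

The unit of inference is one recording session. For each cortical
subregion, three window populations are built on a common relative time
axis spanning −200 ms to +600 ms around a marker (205 samples at
256 Hz):

* **note-onset windows**, time-locked to the retained note onsets;
* **phrase-boundary windows**, time-locked to the 8 expert-annotated
  phrase boundaries (a boundary is also a note onset, so these windows
  additionally contain the onset response);
* **reference windows** of the same 800 ms length, sampled away from
  marker-locked activity to represent ongoing background.

Windows are averaged across the channels of a subregion, the three
populations are bootstrap-equalized to 200 windows each, and each
condition pair (note vs reference, phrase vs reference, phrase vs note)
is compared with a cluster-level permutation test:

1. At every timepoint a two-sided Mann-Whitney U compares the two window
   populations; `U` counts pairs (x, y) with x > y plus half the ties,
   and is converted to `Z = (U − n₁n₂/2) / σ_U` with the tie-corrected
   variance `σ²_U = n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))]`. No
   continuity correction is applied, so Z is a smooth function of the
   rank configuration.
2. Timepoints with |Z| above the cluster-forming threshold — the
   standard-normal two-sided critical value, 1.96 at α = 0.05 — are
   grouped into clusters of temporally adjacent, sign-homogeneous
   suprathreshold points. Opposite-sign neighbours start a new cluster;
   merging them would conflate opposite effects.
3. Condition labels are permuted and steps 1–2 repeated; each
   permutation is summarized by the maximum over its clusters of the
   within-cluster max |Z|. This max-statistic null controls the
   familywise error over clusters within the window. (Since the cluster
   statistic is the within-cluster max |Z|, the per-permutation summary
   equals the global max |Z| whenever it exceeds the forming threshold,
   which is what the implementation computes.)
4. Each observed cluster's p-value is the add-one tail estimate
   `(1 + #{summaries ≥ stat}) / (1 + n_permutations)`; clusters with
   p ≤ 0.05 are significant.

Normality is assessed per timepoint beforehand as a diagnostic —
D'Agostino–Pearson for populations of at least 20 windows (its validity
floor), Shapiro–Wilk below that — but the pipeline always proceeds with
the rank test; iEEG amplitude distributions at single timepoints are
generally non-Gaussian.

### The exchangeable unit of the permutation

Equalizing window counts by bootstrap creates duplicate windows. In the
observed statistic every copy of a source window carries the same
condition label, so the exchangeable unit under the null is the
*source window*, not the bootstrap copy. The default permutation
scheme therefore shuffles labels over the pooled pre-bootstrap windows
and redraws the bootstrap inside every permutation (group sizes stay at
the resampled counts). Shuffling the pooled copies directly is available
as `permutation_unit="window"` for window sets without bootstrap
provenance, but with duplicated windows it is drastically
anticonservative: the duplicate blocks inflate the observed rank-sum
variance relative to a copy-shuffled null, and in simulation the
session-level false-positive rate approaches 1. With the source-level
scheme the measured type-I error on 100 signal-free sessions is ~0.05–0.07
at a nominal cluster-level α of 0.05.

The source-level null is computed exactly but efficiently: after a label
permutation, ranks of the pooled bootstrap sample follow from a
precomputed per-timepoint sort order of the source windows plus the
permutation's copy-count vector (tie groups are the value groups of the
sources), reducing each permutation to O(n₀·T) array work instead of a
full re-ranking. A direct re-ranking implementation is kept as a test
oracle and the two agree to floating precision.

## Preprocessing

Channels whose raw RMS amplitude deviates from the montage median by
more than 2.5 times the across-channel SD of those RMS values are
excluded first. (RMS is the summary of choice; a per-sample reading of
the same rule would exclude essentially nothing consistently.) The
remaining channels are notch-filtered at 60 Hz (IIR, Q = 30), band-passed
1–250 Hz (Butterworth order 4), re-referenced to the average montage,
and decimated to 256 Hz. All filters are zero-phase
(forward–backward second-order sections): ERP latency is the quantity
under study and must not be shifted. Because a 1–250 Hz band-pass
followed by decimation to 256 Hz would alias the 128–250 Hz band, an
explicit anti-alias low-pass at 0.45 × the target rate (order 8) precedes
decimation. Average referencing is the last step before decimation, so
the cross-channel mean is numerically zero (≲1e−14 µV) at the output.

One structural consequence of average referencing is worth noting: any
signal component that is identical on every channel is removed exactly,
and the region average over the *entire* montage is identically zero.
Evoked responses survive only insofar as they are spatially
heterogeneous; both the generator defaults and the validation
experiments are designed with this in mind.

## Stimulus markers

Note onsets are strict local maxima of a nonnegative onset-strength
envelope, subject to a minimum inter-peak gap (50 ms default; the
stronger peak wins within a gap). The weakest half of the candidates is
then discarded — `ceil(keep_fraction · n)` retained, ties broken toward
the earlier peak — because stronger attacks evoke larger responses and
dense weak onsets mostly add overlap between adjacent windows.

Phrase boundaries are annotated on the score and transferred to audio
time through dynamic time warping of score-derived features against
audio features: monotone steps {(1,0), (0,1), (1,1)}, full search band by
default (the sequences are 90 s of frames; a Sakoe–Chiba radius is a
config option), diagonal preferred on backtrace ties. Each annotated
score time maps to the audio frame aligned with its nearest score frame.
The DTW optimum is verified against exhaustive path enumeration for
sequence lengths up to 6.

## Segmentation details

Sample-index mapping is fixed so tests are exact: window centre
`c = round(t·fs)`, `pre = floor(200·fs/1000)` and
`post = floor(600·fs/1000)` samples, inclusive endpoints — 205 samples at
256 Hz. Markers whose window would cross a recording edge are dropped
and counted. No baseline correction is applied by default (a
`baseline_correct` flag exists); the cluster test compares distributions
at each timepoint, so a constant offset affects both conditions alike.

Reference windows are rejection-sampled with two allowed-overlap
fractions, both starting at zero: reference-vs-reference and
reference-vs-note-onset-window. If the target count (44) is not reached,
the reference-vs-reference fraction relaxes first in 0.1 steps to 0.5,
then the reference-vs-note fraction to 1.0, every relaxation logged. At
zero relaxation reference windows are provably disjoint from onset
windows; with naturalistic onset density (~274 onsets in 90 s, windows
spanning −200/+600 ms) the timeline is fully tiled by onset windows and
the sampler must open the note-overlap constraint to produce 44 windows —
the same compromise the original design necessarily made. Reference
windows then still avoid each other, and under the no-effect null they
remain exchangeable with marker-locked windows, which is what the
calibration experiment verifies.

Window-count equalization draws uniformly with replacement (bootstrap)
for both up- and down-sampling, with drawn indices retained for audit.

## IED rejection

Interictal epileptiform discharges (IEDs) are pathological spike
transients; a window containing one is not a valid sample of either
condition. Detection is sliding normalized cross-correlation (Pearson r)
between each channel and a bank of unit-RMS spike templates; local maxima
above `r_threshold` (default 0.8, positive-sign matching by default)
become detections, merged within one template length keeping the higher
score. Matching runs after a zero-phase 12 Hz high-pass of both signal
and template: the smooth 1/f background otherwise reaches chance
correlations above 0.8 with any short template, while a spike's sharp
transient survives the high-pass (measured on clean synthetic sessions:
null max r ≈ 0.75, injected SNR-5 spike scores ≥ 0.92). Rejection
operates on per-channel window stacks before region averaging and before
bootstrap resampling — a window rejected on any channel is gone for good
and cannot be reintroduced by resampling. A detection's rejection extent
is the template half-width plus a 10 ms guard, absorbing the correlation
peak's timing jitter under noise (a couple of samples) so windows that
barely graze a spike cannot slip through.

## Cross-session integration

Statistical inference never crosses sessions (electrode coverage is not
comparable between subjects). Sessions are combined only by counting:
for each subregion and timepoint, the number of sessions with a
significant cluster whose extent contains that timepoint; maximal runs
with count ≥ 6 (light) and ≥ 10 (dark, nested by construction) become
shading intervals; and per-subregion summary rows report the number of
significant clusters pooled over sessions with the mean and SD of their
p-values (population convention, ddof 0; rounded to 3 decimals in
reports). Only significant clusters enter the tables.

## The synthetic session generator

No public recordings exist for this paradigm, so the generator emulates
the statistical structure the analysis assumes:

* **Background**: 1/f^α noise per channel via inverse-FFT spectral
  shaping of white noise (exact spectral control), α = 1 by default — a
  modeling choice, not a measured value — scaled to 10 µV RMS with a
  log-normal (σ = 0.1) per-channel spread. The spread matters: with
  exactly equal channel amplitudes the 2.5-SD bad-channel rule becomes
  degenerate.
* **Markers**: ~274 note onsets over 90 s (truncated-normal
  inter-onset intervals, mean 0.33 s, jitter 0.10 s, floor 50 ms),
  log-normal onset strengths, and 8 phrase boundaries chosen as the
  note onsets nearest to evenly spaced targets — a boundary is also an
  onset, as in real music.
* **Evoked responses**: sums of Gaussian-windowed monophasic components
  (latency, amplitude in noise-SD units, FWHM). Note onsets carry an
  N1–P2-like pair (−1.0 at 100 ms / +1.0 at 200 ms); phrase boundaries
  add a prestimulus component at −150 ms and late components at 400 and
  500 ms. Per-region gains default to a heterogeneous profile (temporal
  cortex strongest, montage mean 1) so that responses survive average
  referencing.
* **Artifacts**: spike transients (sharp 20 ms positive peak plus slow
  negative after-wave, 0.25 s, unit RMS) injected at Poisson times per
  channel (default 0.01 Hz, SNR 5), drawn from the same template bank
  given to the detector — rejection is testable at full detectability.
* **Determinism**: a seed fixes every draw; identical spec + seed gives
  a bit-identical session. Noise, schedule and artifact streams are
  independent, so changing ERP amplitudes changes nothing else.

What the generator does **not** emulate: volume conduction and spatial
correlation between channels (channels are independent noise plus shared
templates), overlap of successive evoked responses beyond what the
marker schedule induces, non-stationary background, realistic IED
morphology variability, and any anatomical geometry. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*,
not the realism of any particular neural claim.

## Validation experiments and problem sizes

The `experiments` module (driven by `scripts/acceptance.py` and the
acceptance tests) recomputes, per run:

* the cluster-forming threshold (analytic);
* Mann-Whitney U against brute-force pair counting (1000 random pairs,
  sizes ≤ 12, ties included) and the exact enumerated U distribution at
  n₁ = n₂ = 6–8, where the continuity-corrected normal p tracks the
  exact two-sided p within 0.01 over the significance-relevant region
  (p ≤ 0.1); the uncorrected approximation is biased by up to ~0.07 near
  the distribution centre, which is why the adequacy check uses the
  standard small-sample correction while the pipeline's Z series remains
  uncorrected;
* type-I error over 100 signal-free sessions, 200 permutations each
  (scaled from the 1000 used in production analyses; the Monte-Carlo
  floor of 1/201 is far below the 0.05 decision level);
* power and latency recovery over 50 sessions with a phrase-boundary
  response (components at −150, 200, 450 ms, amplitude 1.5 × noise SD,
  FWHM 80 ms) injected focally into the analysed subregion. A run counts
  as detected when a significant cluster overlaps 200 ms; a detection
  recovers the component when both cluster boundaries fall within
  ±20 ms of the component's **half-maximum extent** (latency ± FWHM/2) —
  the package's definition of a component's extent;
* spike-detection recall (20 spikes at SNR 5 → 100% recall, zero clean-
  session false alarms, zero contaminated windows surviving rejection);
* plumbing on a sparse-onset session where zero-relaxation reference
  sampling is feasible: window length 205, average-reference residual,
  reference/onset disjointness, bootstrap count, DTW vs enumeration.

All experiment montages use the full eight-subregion, 48-channel default
except where stated; all seeds derive from the single `--seed` argument.

## Known limitations

* Bootstrap equalization to 200 windows does not add information: with 8
  phrase windows the test's resolution is set by 8 effective samples,
  and per-timepoint Z values are correspondingly coarse. The source-
  level permutation keeps the *error rate* calibrated regardless.
* Reference windows in dense-onset material overlap onset windows by
  construction; condition contrasts are therefore against "background
  including unmarked activity", not silence.
* The 2.5-SD bad-channel rule is scale-free but distribution-naive; on
  heavy-tailed montages it can exclude valid channels.
* Detection of IEDs assumes spikes resembling the template bank;
  morphologies far from the bank lower recall, and the 12 Hz detection
  high-pass is tuned to 1/f-type background.
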