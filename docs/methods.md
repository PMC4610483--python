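# Methods

## Problem and data model

A trial is one tracing of a pre-drawn Archimedean spiral on a touch
screen: an ordered sequence of pen samples `(x px, y px, t ms)` at a
nominal 10 Hz over roughly 10 s (~100 samples).  Timestamps are device
milliseconds on disk and seconds in memory.  Coordinates are screen
pixels with y increasing downward; every feature is either invariant to
that convention or measures only magnitudes, and no pixel-to-millimetre
scaling is applied (none is defined for the device class).  Pen lifts
are not encoded; a trial is one continuous stroke, and pauses appear as
slow segments rather than gaps.  Duplicate timestamps are collapsed to
the first sample, since every per-interval quantity divides by the time
step.

## Derived series and features

All series derive from first differences about a configurable origin,
by default the first drawn sample (the template centre may be supplied
when known; the two differ by the subject's start offset, which the
translated fit errors below are designed to isolate).  The radius is
the Euclidean distance from the origin; the angle is the four-quadrant
arctangent unwrapped by cumulative correction of jumps exceeding pi.  A
sample coincident with the origin has an undefined angle and inherits
its neighbour's; for fitting purposes such samples are excluded
entirely.  Per-interval series (speed, radial velocity, angular
velocity, dt) are indexed to the left endpoint.  No smoothing or
resampling is applied.

Feature conventions that the definitions leave open were fixed as
follows:

* **Standard deviations** are sample (n−1) throughout; skewness is the
  biased third central moment over the cubed sample sd, and is 0 for a
  zero-spread series.
* **Wavelet band features** use a 1-level DWT with the Daubechies-10
  wavelet and symmetric (half-sample) boundary extension, which
  minimises edge artifacts on ~100-sample signals; at 10 Hz the detail
  coefficients cover 2.5–5 Hz.  Series shorter than 21 samples (the
  filter support) yield missing values.  `Rv.hf.cv` divides by the
  absolute mean of detail coefficients, which is near zero by
  construction — the feature is heavy-tailed and kept as defined.
* **Approximate entropy** follows Pincus: window length m = 2,
  tolerance r = 0.2·sd of the series, Chebyshev distance, self-matches
  included; a constant series returns 0 (maximally regular).  The
  implementation is vectorised but agrees with an O(n²) double-loop
  enumeration to 1e−10 (tested up to length 200).
* **Extremes** are detected after collapsing runs of equal consecutive
  values to their first element; an interior point is an extreme iff
  its neighbouring differences have opposite signs, and the first and
  last points are always included.  `nPeaks` divides the extreme count
  by the full series length.
* **incDev** computes the delta-peaks of a series, sweeps them with 30
  overlapping windows of length `max(2, len/3)` whose starts are spaced
  as evenly as possible, and reports the Spearman correlation between
  window position and window sd.  A series with fewer than 4
  delta-peaks — notably the monotone radius or angle of any
  well-formed outward trace — carries no measurable variability trend
  and scores 0 rather than missing; treating it as missing would
  discard nearly every trial through the incomplete-row exclusion rule.
* **Rv.pn005** weights intervals by segment path length (not sample
  count); the −0.05 px/s threshold is configurable.
* **TOTSYMM** sums the horizontal and vertical normalised extent
  asymmetries about the origin; a side with no points contributes its
  full asymmetry of 1.  Note that a finite spiral of k turns has an
  intrinsic extent asymmetry of order 1/(2k) per axis — the outermost
  half-turn always protrudes on one side — so even a perfect trace does
  not score exactly 0.
* **Missing values**: a feature whose preconditions fail is emitted as
  nan, and trials with any missing feature are excluded from PCA and
  classification with a logged count.  No imputation is attempted.

## Spiral-fit errors

The drawing is compared with the ideal model `r = a + b·phi` in polar
space about an origin.  `Err` is the RMS radial residual of the
unconstrained closed-form least-squares fit about the first drawn
point, `Err0` the same with the fit forced through the origin (a = 0).
`errBF` and `err0BF` translate the drawing to its *virtual optimal
origin* first: a differential-evolution search (population 20, mutation
0.8, crossover 0.9, at most 100 generations, relative tolerance 0.01,
fixed seed 17, with a final local polish) over the drawing's bounding
box expanded by 25% per side, minimising the respective fit RMSE with
radius and angle recomputed and re-unwrapped about each candidate.  The
constrained error runs its own search: the unconstrained optimum is
generally a poor origin for a spiral forced through zero, and using it
would let `err0BF` exceed `Err0`.  The first-sample origin is always
evaluated alongside the search result, so the translated error can
never exceed its untranslated counterpart.  One caveat: the recovered
angle is only defined up to whole turns (unwrapping anchors at the
first sample's principal angle), so for a trace starting far from the
centre the constrained fit may retain a residual that the unconstrained
intercept absorbs.

## Scoring

PCA uses the correlation matrix: features are z-scored so each enters
with unit variance, zero-variance features are dropped with a warning,
and the eigenstructure is obtained by SVD with a deterministic sign
convention (largest-magnitude loading positive).  Four components are
retained by default; on the default simulated cohort they explain ~71%
of total variance.  Classification uses stratified 10-fold
cross-validation with pooled out-of-fold predictions.  Concrete
classifier settings (fixed across all experiments): MLP with one hidden
layer of `ceil((inputs+classes)/2)` logistic units trained by SGD
(learning rate 0.3, momentum 0.2, 500 epochs); SVMs with C = 1 (RBF
gamma = 1/inputs); unpenalised logistic regression; random forest with
100 trees.  AUC is computed from pooled out-of-fold probability (or
decision-function) rankings with midrank ties.

Sensitivity and specificity condition on the *predicted* class
(column margins of the rater-by-classifier table): sensitivity is the
fraction of predicted-bradykinesia calls the raters confirm, and
specificity the analogue for dyskinesia.  On the published worked
example (28, 8 / 9, 64) this yields 75.7% and 88.9% with accuracy 84%
and kappa 0.65; the conventional row-margin variants are also emitted,
clearly labelled.  Weighted kappa uses linear weights, identical to
Cohen's kappa for two categories.  Reliability statistics are the
literal mean of all pairwise Pearson correlations among raters or among
the three trials of an occasion.

When rated cases feed the classifiers, cases below a mean impairment of
5 (0–10 scale) are excluded, and one eligible rating per case is drawn
uniformly at random so all raters are represented in expectation;
tremor and unidentified ratings are never eligible.

## Synthetic cohort

The simulator emulates the acquisition protocol and the statistical
signatures the features measure — not limb biomechanics.  The pen
advances along the spiral at approximately constant *linear* speed
(`s = pitch·phi²/2` inverted per sample), which matches how people
trace and makes the mean drawing speed a directly controlled quantity;
a constant-angular-rate model would make speed grow with radius and
mask the regularity structure of slow traces.  On top of the nominal
trace (3 turns of a 190 px spiral in 10 s at 10 Hz):

* multiplicative speed noise is band-limited below 0.8 Hz (voluntary
  pace drift is slow);
* bradykinetic trials slow the trace (speed_scale 0.75 on a pitch-4.5
  micrographic spiral, ~54 px/s), insert Poisson-placed arrests
  (expected 3 per trial, 0.8 s each, speed factor 0.05) each followed
  by a 0.5 s festinating burst (factor 1.8), and drift the drawing
  centre rightward in proportion to the radius (bias 0.3), skewing the
  horizontal extent; at least one arrest always occurs, since arrest is
  the defining signature of the condition;
* dyskinetic trials speed the trace up (~289 px/s), widen the pace
  fluctuation (sd 0.25) and add isotropic band-limited (2.5–5 Hz)
  positional noise of 2.8 px sd — placed by construction in the DWT
  detail band, and isotropic because a purely radial perturbation is
  second-order in chord speed and would leave the speed-entropy
  signature flat;
* tremor trials add a 4 Hz radial sinusoid (below the 5 Hz Nyquist
  limit of the device);
* white positional jitter (0.05–0.3 px) models sensor noise.

Preset magnitudes were calibrated once against the characteristic
values reported for rated bradykinetic vs dyskinetic drawings (mean
speed ≈ 56 vs 289 px/s; orderings of detail-coefficient sd, speed
entropy and total asymmetry) and then frozen.  Cohorts draw
between-subject lognormal deviations of speed (sd of the log 0.3) and
of the irregularity/tremor amplitudes (sd 0.2), three trials per
subject, all seeded hierarchically so regeneration is bit-identical.

What passing tests on this cohort do and do not show: the simulated
classes are well separated (the end-to-end pipeline reaches ~100%
cross-validated accuracy at the default settings, versus 76–84% on real
rated drawings), so green end-to-end tests demonstrate that the
pipeline preserves and recovers the class structure it is given — not
that the method achieves any particular accuracy on patient data.  The
simulator also omits pen lifts, pressure, screen quantisation,
device-timing jitter and mixed symptom presentations.

## Problem sizes and numerical choices

Test and acceptance runs use 50 simulated subjects per class (150
trials per class), 10-fold cross-validation, and 40 seed pairs for the
direction checks — sizes chosen to keep the full suite around two
minutes while leaving Monte-Carlo margins far from the thresholds.
Degenerate inputs are handled explicitly: fewer than 2 samples is an
error; zero speed-sd gives skewness 0 and ApEn 0; an all-identical
angle series makes the spiral fit undefined; empty margins make kappa
undefined (nan).  Spearman and kappa statistics come from
scipy/sklearn-equivalent closed forms and are cross-checked against
those libraries in the tests.

## Known limitations

Tremor is simulated but not targeted by any feature: at 10 Hz sampling
the 6–10 Hz action-tremor band aliases, and the feature set is not
designed to quantify it.  The 28-vs-29 feature-count ambiguity in the
original description is resolved by implementing all 29 enumerated
names; PCA consumes whatever the configuration includes.  The
pixel-unit threshold in `Rv.pn005` (−0.05 px/s) is device-dependent and
exposed in the configuration.
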