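# Methods

## ΔF/F estimation

The two-channel trace is reduced to percent ΔF/F by

    ΔF/F(t) = 100 · (F475(t) − (m·F405(t) + q)) / (a·e^(−b·t) + c)

where `(m, q)` is the ordinary least-squares fit of the 405 nm reference
to the 475 nm signal over the whole session, and `(a, b, c)` with `b ≥ 0`
is a nonlinear least-squares exponential fit to the 475 nm signal —
`a·e^(−b·t) + c`, the standard photobleaching model.  The exponential
fit uses variable projection: for a candidate decay rate `b` the
amplitudes `(a, c)` have a closed-form linear solution, so only `b` is
optimized (bounded Brent search on `[0, 100/T]`, absolute tolerance
`1e-12·b_max`).  This makes the fit deterministic, free of
initialization choices, and exactly equivariant under rescaling of the
fluorescence values — the source of the `≤1e-9` rescaling invariance.
A constant reference channel is a degenerate fit; `compute_dff` then
substitutes `(m, q) = (0, mean(F475))` and flags the substitution.

Two structural properties of this estimator are worth knowing:

* **Normalization bias.**  The divisor is fitted to the signal channel,
  so its constant term absorbs the session-mean calcium signal.  The
  recovered signal (and hence every fitted kernel) is scaled by a factor
  of order `1 + mean(ΔF/F)/100`, plus a smaller leakage of residual
  bleach mismatch.  At physiological signal densities this is a ≲0.2%
  relative effect (measured: 2.0e-3 max abs kernel error on a noiseless
  default-amplitude session whose exact-model recovery error is 2e-15).
  Consequently, *exact* (≤1e-6) kernel-recovery checks are run against
  the session's noiseless ΔF/F signal, and the end-to-end error through
  the estimator is reported separately at its measured scale.
* **Artifact removal needs slope ≈ 1.**  A motion artifact added with
  equal amplitude to both channels is removed by the subtraction only to
  the extent the fitted slope is near 1.  The slope is dominated by the
  bleaching covariation of the channels, so the generator gives both
  channels the same bleach kinetics (differing baseline), the regime the
  reference channel exists to provide.  With strongly different
  per-channel bleach amplitudes the subtraction can even amplify an
  equal-amplitude artifact (slope 2 turns `+artifact` into `−artifact`).

For the cross-covariance analyses, ΔF/F is lowpassed with a zero-phase
second-order Butterworth filter (half-power 7 Hz; applied
forward–backward so event-locked features are not delayed) and linearly
interpolated onto the 15 Hz video clock.

## Event-kernel encoding model

One column per (event type, lag) pair, entries = number of events of
that type snapped to the lagged sample (nearest sample; exact midpoints
snap earlier), plus an intercept.  Action kernels span −1…+2 s (46 taps
at 15 Hz), sensory kernels 0…+2 s (31 taps).  The model grid is the
15 Hz post-interpolation grid.  OLS is solved by SVD (`gelsd`) with a
relative singular-value cutoff of 1e-8: in this task the tone often
terminates exactly at the crossing, so tone-offset and crossing columns
can be collinear; the cutoff yields the minimum-norm solution over the
unidentifiable directions (logged) instead of exploding coefficients.

ΔR² of an event type is R²(full) minus the mean R² of reduced models in
which that type's event times are redrawn uniformly over the session and
*all* kernels are refitted.  Default 20 shuffles with mean aggregation;
the per-fit seed derives from the session seed.  Shuffled times are not
constrained to the trial structure.

## Cross-covariance

Per segment: `c(ℓ) = (1/N)·Σᵢ (x[i+ℓ] − x̄)(y[i] − ȳ)` for ℓ up to
±2 s on the 15 Hz grid (±30 samples), summarized by the signed value of
largest magnitude (ties keep the earlier lag).  The `1/N` ("biased")
scaling was chosen over raw sums because segments differ in duration —
unscaled sums grow with segment length and produce a spurious step
between the long habituation chunks and the shorter inter-trial
segments; correlation normalization was measured and rejected because
within-segment ΔF/F variance is dominated by the movement-locked
transients themselves, which cancels exactly the coupling-strength
changes the trial-evolution analysis is meant to expose.  Raw (`none`)
and correlation (`normalize=True`) modes remain available.  Segments run
from 5 s after tone offset to 5 s before the next tone onset; segments
shorter than 61 samples are dropped; the pre-task habituation period is
processed as its own segment set, chopped into ~40-s chunks so its
segments are commensurate with inter-trial ones.

## Behavior detectors

* **Open field:** the movement threshold comes from k-means (k = 3,
  10 restarts, seeded) over instantaneous speeds; clusters are ordered
  by centroid and the threshold is the minimum speed among members of
  the middle cluster, which makes it invariant to k-means label
  permutation.  Epochs are speed peaks with height ≥ threshold and
  prominence ≥ 5 cm/s; initiation is the earliest time within 2 s before
  the peak at which speed exceeds 10% of the peak (none if the speed
  never drops to that level in the window); at least 1 s below threshold
  must precede initiation, with time before the trace treated as still
  so that prepending quiet padding cannot change the epoch list.
* **Inter-trial:** speed is smoothed with a 7-frame Gaussian-weighted
  moving average (σ = window/5 = 1.4 samples, truncated-renormalized at
  the edges; an isolated single-frame 30 cm/s spike smooths to
  8.6 cm/s, below the height rule).  Peaks need absolute height
  > 10 cm/s and prominence ≥ 3 cm/s; a peak within 5 s after a kept one
  is excluded, greedily in time order.  Windows span 5 s after each
  trial's end to 5 s before the next tone onset.
* **Freezing:** the silhouette is pixels darker than 27/255; the
  movement signal is the count of silhouette pixels changed between
  consecutive frames.  The detector's nominal band is 0.01–0.9
  (fractions of Nyquist at 15 frames/s).  Only the 0.9 lowpass
  leg is applied by default (zero-phase Butterworth): the 190-pixel rule
  is an *absolute level* threshold, and a 0.075 Hz highpass (τ ≈ 2 s)
  strips the sustained component from any bout or movement stretch
  longer than a few seconds, which inverts the classification of long
  bouts.  The highpass leg is available behind
  `DetectorParams.freeze_highpass` for data whose slow illumination
  drift requires it.  Frames with filtered counts below 190 are
  freezing; the first frame inherits the second's label.  Both pixel
  constants are resolution-dependent and therefore configurable.
* **Trial scoring:** crossings come from the event table or, failing
  that, from midline sign changes of the tracked position with 1 cm
  hysteresis.  A crossing within the 5-s window scores avoid (approach,
  or omission when no reward lick follows, in the reward task); within
  the 2-s shock, escape; otherwise fail.  The freezing-to-latency ratio
  counts freezing frames in `[tone_on, crossing)` only; shock-period
  frames are not counted.

## Group statistics

Animals are the unit of analysis: per-trial quantities are averaged per
animal before any test.  The peri-crossing contrast compares mean ΔF/F
over `[−4, −2)` s with `[−1, +1]` s (half-open pre window so no sample
is double-counted), paired t across animals.  Trial-amplitude
correlations use max ΔF/F in `[−0.5, +1]` s and max speed in
`[−0.5, +0.5]` s around the crossing, Pearson r per animal (animals with
fewer than 3 successful trials are excluded), one-sample t across
animals.  The optogenetic speed analysis averages speed in the 0.5–2.5-s
stimulation window per trial (trials crossing before the window opens
are excluded), reduces to per-animal stim/no-stim means, and tests the
opsin × stimulation interaction in a two-way ANOVA.  Crossing latencies
are binned at 0.25 s over 0–7 s and normalized by the condition's total
trial count; the stimulation-window ratio divides the summed
probability inside 0.5–2.5 s under illumination by the same without.
Block-structure series support the off6+on6, on6+post6 (first off and
last on block excluded) and pre3+on6+post3 chunkings.  The
repeated-measures ANOVA uses Tukey HSD as the post-hoc procedure; it is
cross-checked against an independent implementation in the tests.

## Synthetic generator

The generator emulates the study's sessions with every hidden parameter
recorded: tone-triggered trials with a 5-s window, 2-s shocks, ITIs
uniform on `[0.5, 1.5]·40 s` ("pseudo-random with a 40-s mean"), 10%
short/long special tones or reward omissions, 72-trial/12-block
stimulation designs, and a first-day variant with a 5-min habituation
and two tone–shock pairings.  Crossing latencies follow a shifted
log-normal (0.5 s + lognormal(median 2 s, σ = 0.9) → ~80% avoidance,
a trained animal); stimulated trials can be slowed (latency shift,
speed factor) to emulate the opsin effect.  Calcium kernels default to
a difference of exponentials (rise 0.1 s, decay 0.6 s — indicator-like
dynamics), peak-normalized; action kernels peak at the event, sensory
kernels after it; amplitudes default to 1.5% (avoid), 1.2% (ITI
crossing), 1.0% (escape), 2.0% (shock), 0.3% (tone on), 0 (tone off).
Movement-locked kernels of events after the first shock are multiplied
by `post_shock_gain`, the mechanism behind the coupling-step analyses.
Photometry is the generative inverse of the ΔF/F model: multiplicative
bleach on the signal channel, additive shared band-limited (≤1 Hz)
Gaussian artifact, independent white measurement noise (0.3 raw units
≈ 0.1% ΔF/F at the ~300-unit baseline).  Speed is built from Gaussian
bumps (σ = 0.4 s) at crossings and at spontaneous movement epochs drawn
as a Poisson process at 1/15 Hz with an 8-s minimum gap; the midline
position flips sign smoothly at every crossing.  Synthetic videos are a
dark disk (radius 12 px, intensity 10) on a light background that jumps
≥ 6 px per frame except during freezing bouts, reflecting at the walls
so a jump is never absorbed by clipping.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: channel-specific bleach
kinetics and hemodynamic or wavelength-dependent artifacts (the
isosbestic subtraction is exercised in its favorable slope≈1 regime);
non-stationary kernels, adaptation, or indicator nonlinearity;
tracking noise structure beyond white speed noise; video backgrounds
with texture, shadows, or multiple dark objects.  Recovery on real
recordings depends on how far those assumptions are violated.

## Numerical choices and degenerate inputs

Events are snapped to the nearest grid sample with midpoint ties broken
toward the earlier sample.  Rank-deficient encoding designs fall back to
minimum-norm with a logged warning rather than an error.  Constant
segments give all-zero cross-covariance (documented, not an error).
Zero-latency trials are skipped in the freezing ratio with a log entry.
Session CSVs are written with `%.17g` and parsed with round-trip float
precision, so `read(write(session))` is bitwise exact.  All randomness
flows from explicit integer seeds through `numpy.random.Generator`;
cohort and stage seeds are derived child seeds, so any artifact is
recomputable from `(config, seed)`.

## Problem sizes

The test and reproduction runs use cohorts of 8 (plus 5 controls for
optogenetics), 20–30 trials per photometry session, 72 trials per
optogenetic session, 600-s recovery sessions at 15 Hz, 120-s videos at
15 frames/s, 20 shuffles per ΔR², and 10–100 seeds per Monte-Carlo
check — sizes at which every qualitative effect the generator encodes is
resolvable with margin while a full run stays within minutes on one CPU.
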