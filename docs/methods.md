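# Methods

## Signal model and filtering

The input is a two-channel acceleration time series from a single inertial
sensor at the lower lumbar spine (L5–S1), taken as a proxy for the
centre-of-mass acceleration: vertical (`a_vert`, gravity-positive baseline
9.81 m/s²) and anteroposterior (`a_ap`), uniformly sampled at `f` = 200 Hz.
Both channels pass through a fourth-order Butterworth low-pass filter applied
forward and then backward (`scipy.signal.sosfiltfilt`, reflective padding of
3 × order samples). The two passes cancel the phase shift — essential because
all downstream quantities are event *times* — and square the magnitude
response (an effective eighth-order roll-off). Cut-offs are 20 Hz (vertical)
and 30 Hz (anteroposterior); the AP channel keeps more bandwidth because the
heel-strike transient is sharper. Note that the filter is the standard
bilinear-transform digital design, so its stop-band response follows the
prewarped frequency ratio `tan(πf/fs)/tan(πfc/fs)` rather than the analog
`f/fc`; the tests assert against the digital response.

Timestamps must be uniform within `max(1e-6 s, 0.01/f)` — real loggers
jitter slightly — and a missing time column is synthesized as `k/f`.

## Event detection

Heel strikes are local maxima of the filtered AP channel after discarding a
10 s warm-up (the athlete's acceleration phase), with three gates, all
config-overridable since no canonical parameter set exists:

* minimum separation 0.25 s (= the 4 steps/s upper cadence bound);
* height ≥ median + 1.0 × IQR of the post-warmup AP signal;
* prominence ≥ 2.0 m/s². Trunk heel-strike transients reach several m/s²
  while filtered sensor noise stays an order of magnitude below; without a
  prominence floor, noise-only recordings would yield spurious "steps".

The vertical minimum (NPVA) is the earliest minimal sample strictly inside
each consecutive heel-strike pair (earliest-sample tie-break for
determinism). Steps whose cadence falls outside the valid elite range
[2.8, 4.0] steps/s are flagged and excluded step-wise, never aborting a
trial.

## LOGC timing

Per step, `LOGCT_i = tmax_{i+1} − tmin_i − E(SC_i)` with the cadence-dependent
threshold `E(SC) = SC²/a + SC/b`, `a = −40.921`, `b = 11.242`. `E` decreases
from ≈57 ms at 2.8 steps/s to zero at `SC = −a/b ≈ 3.640` steps/s; negative
raw values are clamped to zero, since the threshold is a duration.
`LOGCT ≤ 0` marks double support. Timing bounds are `LOGCT ± 2/f`: one
sample of uncertainty attributed to each of the two detected events, which
also fixes the fuzzy band half-width below. Sequence values are unweighted
arithmetic means over consecutive, non-overlapping windows of exactly
NS = 30 steps (the judge's field of view); the trailing remainder is dropped
with a warning, and double-support steps contribute their actual (≤ 0)
values.

### Refitting the threshold

`fit_threshold_model` recovers `(a, b)` from per-step optimal thresholds
(the `E` that would zero the inertial-minus-benchmark difference) by
ordinary least squares on the intercept-free basis `[SC², SC]`, with three
exclusion rules: cadence outside [2.8, 4.0]; negative OT (toe-off cannot
precede the vertical minimum); and points outside the 99% prediction
interval, applied iteratively until the included set is stable (a single
pass is the first iteration, so noiseless recovery is exact). A
least-absolute-residual variant (median regression, `statsmodels.QuantReg`)
is reported alongside, as robust fits of this model are customary; R² is
reported in percent for both. All SC values are excluded/fit on the raw
scale; no weighting.

## Classification

With LHE = 40 ms, equality resolves toward the athlete throughout:

* **binary** — legal iff timing ≤ LHE;
* **three-level** — legal iff the `[min, max]` interval sits at or below
  LHE, illegal iff strictly above, doubt when it straddles the limit;
* **fuzzy** — membership η = 0 at or below LHE − 2/f, 1 at or above
  LHE + 2/f, linear in between (η = 0.5 exactly at LHE). At 200 Hz the doubt
  band is (30, 50) ms. The ramp is taken linear: the plateau edges pin the
  function and a straight interpolant is the minimal choice.

The infringement fraction of a sequence counts binary-illegal steps over
NS — an ungraded count, so it deliberately consumes binary labels only.

## Performance parameters

Cadence `SC = 1/(tmax_{i+1} − tmax_i)`; step-length ratio
`SLR = 100·v/(SC·h)` percent, with the trial mean speed `v` an external
input (course markers / GPS, not derivable from the sensor) and `h` the
stature. Smoothness is the dimensionless jerk cost of the AP channel over
one step window,

```
S = T⁵ · (SC/v)² · ∫ j²(t) dt,        T = 1/SC,
```

`j` by central differences (one-sided at window edges), trapezoidal
integration. The `(SC/v)²` factor divides by the squared step length, the
unique reading that renders `S` dimensionless and lands realistic inputs in
the [1, 10] normalization band; the alternative `1/(SC·v)²` scaling remains
available behind a flag for sensitivity analyses. Discretization error
against the sinusoid closed form `2π²A²/(SC²v²)` is ≤ 2% at 200 Hz.

## Indices and radar score

δ is the single line through the three anchor points
(LHE − 2/f, 0), (LHE, 0.4), (LHE + 3/f, 1) — they are collinear with slope
f/5 — clamped to [0, 1]. α is the infringement fraction. γ and ρ are linear
shortfalls against elite-competition speed correlations
(`SC = 0.259·v[m/s] + 2.253`, `SLR = 2.47·v[km/h] + 32.73`): the value at
the qualifying-standard speed (12.20 km/h = 3.39 m/s) maps to 0.4, the value
at the record speed (printed as 15.76 km/h / 4.38 m/s) maps to 0, clamped to
[0, 1]. μ maps smoothness linearly from [1, 10] to [0, 1].

Two calibration wrinkles are handled explicitly. First, the published unit
annotations of the two correlations are swapped relative to the anchor
values they are said to produce; the assignment above is the one that
reproduces the published anchors (3.130 steps/s and 62.8). Second, the
published record speed is slightly inconsistent with the published optimal
anchors (4.38 m/s gives 3.387 steps/s and 71.66, vs the printed 3.380 and
71.4, which imply ≈ 4.35 m/s). The package defaults to the printed anchors
and lets `calibrate_boundaries` recompute them from any speed pair.

The radar chart plots `r_k = 1 − index_k` (wider pentagon = better) on axes
at 90° + k·72°, in the fixed order (α, δ, μ, ρ, γ) — infringement axes
grouped right, performance axes left. ε is the shoelace area over the
regular unit pentagon's area `(5/2)·sin 72° ≈ 2.3776`. The axis order is
recorded in the profile because the polygon area depends on it; alternative
orders can be passed explicitly. ε_opt is the largest ε among profiles with
δ ≤ 0.4 and α ≤ 0.4; with no admissible profile the result is an explicit
empty value, not an error.

## Benchmark and agreement statistics

The 240-fps camera reference uses four frame numbers per step (last contact
frame FNA, FNB = FNA + 1, last airborne frame FNC, FND = FNC + 1):
`LOGCB_max = (FND − FNA)/FR`, `LOGCB_min = (FNC − FNB)/FR`, a width of
exactly two frames; the central value is the interval midpoint, which
realizes the "toe-off frame to following heel-strike frame" definition
within half a frame. The benchmark membership λ uses the same trapezoid and
the same 2/f band as η (the inertial sample frequency, so the two
memberships share a scale). σ = η − λ; |σ| < 0.5 is an acceptable
classification and τ is the acceptable fraction, with |σ| = 0.5 counting as
wrong.

Binary confusion statistics take **legal** as the positive class — the
convention under which false alarm = 1 − TPR and miss alarm = FPR, matching
the published summary relations: false alarm = P(illegal call | truly
legal), miss alarm = P(legal call | truly illegal). Rates over an empty
truth class are NaN, never zero. The precision–recall construction takes the
per-class (TPR, PPV) points, prepends the (0, 1) anchor, sorts by recall and
integrates by trapezoid. Hedges' g uses the pooled SD and the small-sample
correction `J = 1 − 3/(4N − 9)`; index weights κ are `|g|` normalized to sum
to one (signless weights, as a share-of-influence decomposition requires).

## Synthetic data generator

`generate_trial` emulates what the trunk sensor sees, not full-body
dynamics: raised-cosine pulses (exact, analytically placed extrema) on the
AP channel at each heel strike (default 8 m/s² amplitude, 25 ms half-width)
and subtracted from the 9.81 m/s² vertical baseline at `TOE − E(SC)`
(12 m/s², 30 ms half-width), plus seeded Gaussian sensor noise (default
0.3 m/s²). Defaults mirror the study conditions: 200 Hz, 14.0 km/h,
3.29 steps/s, 45 ms flight, stature 1.745 m, 10 s warm-up before the judged
steps. Placing the vertical minimum at `TOE − E` embeds the estimator's own
timing model deliberately: recovery tests then isolate detector and sampling
quantization error (≤ 2/f noiseless) from model error, which real data would
confound. Consequences to keep in mind: the generator cannot falsify the
threshold model itself, its waveforms are cleaner and more periodic than
athlete data (no drift, no asymmetry, no soft-tissue artefacts), and its
smoothness values sit near the top of the [1, 10] band. Passing recovery
tests demonstrates correctness of the pipeline mechanics, not field accuracy.

Video annotations quantize the true toe-off/heel-strike instants onto the
frame grid (`FNA = ⌊TOE·FR⌋`; `FND = ⌈HSE·FR⌉`, next frame when exactly on
the grid), which guarantees the benchmark interval brackets the true flight
time. A flight shorter than one frame that falls entirely between two frames
has no airborne frame; the annotation is bumped to `FNC = FNB` (zero lower
bound), the call an annotator convinced of flight would make. Zero flight
sets the no-flight flag.

## Problem sizes and numerical choices

Tests run on trials of 20–75 s (≈ 30–210 judged steps) and ten noise seeds
where distributional claims are made; these sizes give stable statistics for
every asserted property while keeping the suite fast. Peak-detection,
tie-break and clamping rules are deterministic by construction; all
randomness flows through explicit seeds (`numpy.random.default_rng`), and a
fixed spec + seed reproduces a trial byte-for-byte in CSV export.

## Known limitations

* Bent-knee infringements, left/right foot attribution and stance sub-phases
  are out of scope; only LOGC is computed.
* The threshold model is calibrated for elite athletes within
  [2.8, 4.0] steps/s; outside this range cadences are clamped with a warning
  and results should not be trusted.
* Mean speed is an external input; without it the step-length ratio and
  smoothness normalizations are undefined (judge mode does not need them).
* The per-competition normalization of indices (men/women, 20/50 km) is not
  implemented; the calibration constants are global.
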