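# Methods

This note records the models, parameter choices and numerical conventions
behind `vplmouse`, and what the synthetic test bed does and does not
establish about real water-task data.

## Observer model

Choices are Bernoulli draws from a logistic 2AFC psychometric function on
the log₁₀ stimulus axis. The guess rate is fixed at 0.5 (two-alternative
task) and the default lapse rate is λ = 0.02, small enough that shaping
performance of "90% or better" on easy stimuli is attainable. The function
is parameterised directly by its 70%-correct level α, so group thresholds
from the literature map one-to-one onto model parameters without
conversion: the logistic offset is b₀ = logit((0.70 − γ)/(1 − γ − λ)).

**Slopes.** Water-task frequency-of-seeing curves fall from near-ceiling to
chance over roughly 0.1 log unit near threshold. We encode this as: the
chance→lapse-limited transition (≈ 4 logits) spans about two assessment
steps. One step is 0.10 contrast (≈ 0.14 log₁₀ near the naive threshold)
and 0.03 cpd (≈ 0.027 log₁₀ near 0.47 cpd), giving default slopes
β_contrast = 12 and β_sf = 36 per log₁₀ unit. Estimator validation showed
why this matters: against a much shallower observer the staircase's
"first crossing from the easy end" read-out acquires an easy-side bias of
about one step, because sampling noise creates spurious sub-criterion dips
at levels where true accuracy is only slightly above 70%.

**Between-animal variability.** True thresholds are log-normal around the
group calibration value. For the calibrated presets the spread (0.05 log₁₀
units) was derived from printed SEM·√n (e.g. CS 0.11·√21 ≈ 0.50 on 3.75)
less headroom for measurement noise added by the staircase itself;
uncalibrated presets use 0.04. A single per-animal offset shifts the start
and asymptote of every learning pathway together, which keeps
post/pre-ratio spreads narrow, as observed.

**Presets.** `naive`/`control` (CS 3.75 → 7.05 at 0.33 cpd; VA 0.47 →
0.72 cpd), `nct_trained`, `nsft_trained` (post-training state; the trained
CS value at 0.33 cpd for SF-trained animals is taken comparable to the
contrast-trained asymptote, as no group mean is published), `amblyopic`
(deprived eye 0.28 → 0.47 cpd, fellow eye 0.46 → 0.48 cpd; the deprived
eye is `"left"` by convention), and `old` — an **uncalibrated
placeholder** (0.38 → 0.60 cpd, tripled time constant) because no numeric
baseline exists for aged animals. Contrast thresholds at non-reference
spatial frequencies are interpolated along a log-parabola CSF anchored at
the two published naive points (CS 3.75 at 0.33 cpd, 4.59 at 0.21 cpd)
with width 1.5 (log₁₀CS per log₁₀cpd²), chosen to give a realistically
broad rodent CSF (CS ≈ 2 at 0.06 cpd); where the parabola dips below
CS = 1 the contrast threshold is clamped to 1.

## Learning rule

Effective dose counts non-correction trials within 0.3 log₁₀ units of the
current trained threshold (factor ≈ 2), so 100%-contrast or 0.12-cpd
control trials contribute nothing. The trained threshold follows
α(d) = α∞ + (α₀ − α∞)·e^(−d/τ) with τ = 200 near-threshold trials: 35 days
× 2 sessions × 10 trials saturates the curve (> 95% of the span), while at
18 days a 4-session schedule is still visibly ahead of a 2-session one,
matching the qualitative dose–response contrast in the source data. The
day-18 group percentages themselves depend on unprinted per-animal values
and are checked directionally only.

Transfer is expressed on **fractional progress**: an untrained pathway
moves along its own start→asymptote span by f·u, where u is the trained
pathway's progress and f the product of an interocular fraction (0.63,
consistent with 67% vs 42% trained/untrained-eye improvements), an
asymmetric task fraction (pattern→detection 0.90, detection→pattern 0.07,
the published transfer indices), and a cross-domain fraction (1.0 —
contrast-trained animals gained VA at essentially the full NSFT rate).
Progress-scaling was preferred over raw log- or linear-threshold shifts
because it keeps every threshold inside its physical span under any update
sequence and makes a simulated transfer index approximate f directly.
Orientation is not a learning dimension (TI ≈ 0.96 between orthogonal
orientations), so thresholds are orientation-independent. Retention decays
progress with a 65-day half-life, consistent with 74%/63% retention at
28/45 days; it is a loose calibration, not a fitted value.

## Assessment procedure

Criterion blocks are sequential with early stopping at the 4-streak or the
7th hit; failure is only declared at the 10th trial. Correction trials
(same level and side, repeated until correct) are logged but excluded from
criterion evaluation and FOS accuracy — they follow forced repeats at a
known side. Inclusion is available via a flag. The probability that a pure
guessing observer passes one block is 294/1024 ≈ 0.287 (exhaustive
enumeration), so undefined thresholds are detected by repeated failure at
the easiest level (3 failures before any pass) or by a pooled easiest-level
accuracy below criterion with at least a block of trials.

"Stable pattern of performance" is operationalised as: at least four
preliminary thresholds (descent-failure reversals) with the last two within
one step. This yields ≈ 185–240 scored trials per assessment, matching
8–9 testing days at ~20 trials/day, and empirically removes most of the
staircase's finite-sample bias (residual |bias| well under one step across
α grids in both domains; a small high-side bias of ≈ +0.15 on group CS
remains from the convexity of CS = 1/threshold over the coarse 0.1-contrast
grid, and is inside the 2-SEM band of a 21-animal cohort).

Threshold read-out: linear interpolation between the adjacent tested levels
bracketing the first ≥70% → <70% crossing scanning from the easy end; a
level at exactly 70% is itself the threshold. An isotonic-regression mode
(accuracy regularised to be non-increasing in difficulty before
interpolation) is available; it trades the easy-side dip sensitivity for a
hard-side bias and is not the default. Session bookkeeping is 10 scored
trials per session, 2 sessions/day (configurable to 4). The SF staircase
uses the same 0.03-cpd step in both directions; the level grid is capped at
1.5 cpd (far above murine acuity) and 100% contrast.

## Training protocol

Within a training day the level tracks the observer's current 70% point
using the same criterion blocks and steps as assessment (one step easier on
fail, one harder on pass); blocks truncated by the 10-trial session
boundary leave the level unchanged. Learning state updates after every
session. The daily trajectory value is the threshold re-estimated from that
day's own ~20–40 trials; when the day's FOS never crosses 70% the hardest
(or easiest) level visited bounds the threshold and is reported instead.
The post-training value is the arithmetic mean of the final four daily
values. Control regimens hold the easy level fixed; their daily logs
contain no crossing, so their pre/post values come from standard
assessments run before and after the 35 days — mirroring the pre/post
testing sessions of the study design — and their daily values are NaN.

## Imaging

Synthetic cortices render a Gaussian responsive patch (σ = 0.22 of the
image) on a unit-reflectance background at 5 frames/s (acquisition rate is
a package choice; all windows are specified in seconds and rounded to
frame centres). Episodic trials are 1 s baseline + 4 s stimulus + 7 s gap;
the hemodynamic time course ramps over 2 s, is exactly 1 inside the 2–6 s
post-onset analysis window (so the embedded fractional response is
recovered exactly by the ΔR/R algebra), and decays afterwards. The evoked
fractional reflectance decrease declines linearly in SF to zero at the true
cut-off (0.39 cpd trained, 0.27 cpd untrained/naive presets) with peak
amplitude 2×10⁻³; per-pixel white noise (σ = 2×10⁻³) and a slow global
drift (10⁻³, 137 s period) are added, in the scale range typical of
intrinsic signals. Frames are stored float32.

Analysis: per-trial ΔR/R maps, trial averaging over 32 trials, disk
smoothing (radius 3 px = 51 μm at 17 μm/px) with renormalised partial
kernels at borders, ROI = top decile of the smoothed lowest-SF response,
tuning reported as positive response magnitude, and OLS zero-crossing for
the cut-off. The fit uses conditions above a noise floor plus the first
subthreshold condition; the floor is operationalised as twice the median
(across conditions) SEM of per-trial ROI responses, since no separate
blank condition is acquired. Including the first subthreshold point biases
the recovered cut-off upward by ≲ 0.01 cpd (the generator clips negative
responses to zero); recovered means are 0.393/0.285 cpd for truths
0.39/0.27 over 10 animals — inside the ±0.03 band used for validation and
strictly ordered. Retinotopy: per-pixel complex amplitude at the 0.1 Hz
stimulus frequency (magnitude and phase maps); map quality is scored as
the mean absolute circular deviation of each suprathreshold pixel's phase
from its local disk-mean phase (the pixel participates in its own
neighbourhood, so the uniform-phase reference value is ≈ 1.36 rad, below
π/2). Opposite sweep directions can be combined by phase averaging to
cancel the hemodynamic delay.

## Group statistics

Group metrics default to per-animal computation then averaging (mean ±
SEM, sample SD, SEM = 0 by convention for n = 1); a group-means mode
applies the formulas to group means directly — the transfer index is
necessarily computed this way because the naive comparison is a different
cohort. The two modes differ whenever animals vary, which is why published
group improvement percentages need not equal arithmetic on the published
group means (e.g. 87% vs 88% for CS); both are exposed.

## Problem sizes and reproducibility

Validation cohorts use the study's group sizes (21, 42, 15 animals; 10
imaging animals); property checks use 40–300 simulated observers and
16–64 px stacks, sizes at which the checked statistics are stable. One
master seed drives everything; per-animal streams derive from
`SeedSequence((seed, animal_id))`, so cohorts are bit-reproducible and any
animal can be regenerated in isolation.

## What the synthetic test bed does not show

The generator realises exactly the psychometric and learning structure the
analysis assumes: logistic choice curves, stationary thresholds within a
day, lapses independent of state, learning driven only by near-threshold
trial counts, and linear SF tuning of the cortical response. Passing tests
therefore validate the *procedures* (staircase logic, threshold read-out,
formulas, imaging pipeline) and their statistical behaviour under the
calibrated conditions — not the biological claims. Real data add
motivational drift, side biases beyond the scheduler's control, vascular
artefacts and non-linear tuning shapes that this generator deliberately
omits. Inferential statistics (ANOVA families, post-hoc tests) are out of
scope; the pipelines emit tidy per-animal tables for any statistics
package.
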