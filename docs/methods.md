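# Methods notes

This note documents the models behind the pipeline, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer should know about. No empirical claim
here goes beyond what the test suite and `scripts/acceptance.py` compute.

## Coordinate conventions and geometry

Gaze positions are degrees of visual angle from the screen center, +x
rightward, +y upward. Pixel coordinates follow the image convention (origin
top-left, +y down); the conversion handles the y-flip. The mapping is
linear (small-angle): stimulus sizes are specified as flat visual angles
and no screen-curvature treatment is attempted; over an 18.4 x 13.8 deg
display the tangent correction would be well under a percent. The angular
extent (18.4 x 13.8 deg at 75 cm) is the physically meaningful part of the
geometry; the default 1280 x 960 pixel raster is an arbitrary anchor for
pixel-unit inputs, chosen so horizontal and vertical pixels-per-degree
coincide (69.57 px/deg).

## Event detection

Velocity is a moving-average derivative: for half-window k (default k = 2,
i.e. 5 samples), `v_n = sum_{j=1..k} (x_{n+j} - x_{n-j}) / (dt * k * (k+1))`.
Edge samples use shrunken symmetric windows down to a one-sided difference
at the boundary. Samples whose window touches a missing-pupil sample have
undefined (NaN) velocity and cannot seed events.

The per-trial robust scale is `sigma = sqrt(median(v^2) - median(v)^2)` per
component, computed over the whole trial (saccadic samples included — the
median makes their influence small). The default criterion is elliptical,
`(v_x/eta_x)^2 + (v_y/eta_y)^2 > 1` with `eta = 6 * sigma`; a scalar
criterion on speed is available (`criterion="scalar"`) since the two are
both defensible readings of a velocity threshold.

The 12-ms rule is applied twice, deliberately: candidate runs must last at
least 12 ms (offset minus onset), and events separated by less than 12 ms
merge. Both are independently configurable because "intervals longer than
12 ms" admits either reading; applying both is the conservative choice.

Saccade classification requires *sustained* speed above 35 deg/s for the
minimum duration plus a peak |acceleration| above 9500 deg/s^2 within the
event. A literal per-sample conjunction of the two criteria would never
fire for a ballistic waveform — acceleration crosses zero exactly where
speed peaks — so the sustained-speed + acceleration-peak reading is used.
Blinks are missing-pupil spans; saccadic runs overlapping a span (within
the merge gap) are absorbed into one blink event, mirroring tracker
semantics where a blink is a missing pupil during a saccadic transient.
An optional amplitude cap for microsaccades exists but is off by default.

Processing is monocular; no binocular-agreement criterion is applied.

## Synthetic gaze traces

The trace generator is built for detector validation, not biological
completeness. It superimposes:

- **Drift**: a Gaussian random walk with scale `drift_sd_deg_per_sqrt_s`
  (default 0.025 deg/sqrt(s)) per component.
- **Microsaccades**: Poisson onsets at `ms_rate_hz` (default 1.5 Hz, a
  literature-typical fixational rate), lognormal amplitudes with median
  0.26 deg and log-SD 0.55 — so roughly 88% of injected amplitudes fall
  below 0.5 deg, in the range reported for fixational eye movements — and
  a raised-cosine velocity profile (smooth, symmetric, zero endpoint
  velocity). With that profile, amplitude A, duration T and peak velocity
  Vp are linked by `A = Vp * T / 2`, so the duration is derived from the
  main-sequence slope: `T = 2 / slope`. The default slope of 90 /s gives
  22-ms events with Vp = 90 * A, inside the physiological main-sequence
  band; it also keeps default events clearly separated from the saccade
  criteria (a 0.26-deg event peaks at ~23 deg/s). A slope of 60 /s was
  considered and rejected: it forces 33-ms events whose threshold-crossing
  time lags the true onset by more than 5 ms over a large fraction of the
  amplitude distribution, which would make onset-accuracy validation
  meaningless. The horizontal sign of each event matches the cue side with
  probability `toward_cue_prob` (default 0.70); orientation scatter around
  the horizontal axis is Gaussian (SD 0.35 rad).
- **Refractoriness**: injected events keep a 30-ms gap after the previous
  event's offset. Conflicting onsets are redrawn rather than thinned, so
  the total count remains Poisson; without this, closely spaced injected
  events would be merged by the 12-ms rule and recovery could not be
  scored event-by-event. Real intersaccadic intervals show comparable or
  longer refractoriness.
- **Blinks**: with probability 0.011 per trial (matching the exclusion
  rate such studies report), one 150-ms missing-pupil span at a uniform
  time.
- **Sensor noise**: white Gaussian, default SD 0.0015 deg.

The drift and noise defaults are *cleaner than real recordings* (a good
video tracker has RMS noise nearer 0.01 deg and drift is faster and
mean-reverting). They were set so that the lambda*sigma threshold sits well
below the main-sequence velocities of study-scale amplitudes, which is the
regime the recovery guarantees (>= 90% of injected events found with
onsets within 5 ms) are stated for. Passing those tests therefore shows the
detector implements its rules correctly and recovers events under
favorable noise; it does not bound detector performance on real data,
where small-amplitude recovery will be worse. There is also no mean
reversion in the drift, so a few percent of simulated trials wander past
the 1.5-deg fixation bound and are excluded — harmless for the analyses,
and it exercises the exclusion path.

## Synthetic behavior

Each subject's base sensitivity is `d_s ~ N(0.95, 0.40)` truncated at zero
(values matching the hit/false-alarm ranges typical of this paradigm with
criterion c = 0.77, giving hit rates near 0.58 and false alarms near 0.22).
On target-present trials the internal signal is
`N(d_s + effect/2, 1)` (valid cue) or `N(d_s - effect/2, 1)` (invalid);
target-absent signals are `N(0, 1)`; the response is "present" above c.
Trial composition is exactly balanced within each subject x condition x SOA
cell (60 trials: 30 present, 15 valid / 15 invalid) rather than binomially
random — the fixed design of a blocked experiment. The default
`cue_effect_dprime` structure is the study-scale one (intact 0.31/0.41,
floating heads 0.29/0.05, headless bodies 0.22/0.07 for SOA 200/500); the
packaged demonstration config instead uses a single round magnitude of
0.35 in every transient cell and the intact sustained cell, and exactly 0
elsewhere, to make the qualitative sustained-vs-transient pattern the
object of the end-to-end check.

A note on estimator bias: the per-subject d' uses `Phi^-1` of a proportion
from few trials (15 per validity at study scale). `Phi^-1` is convex above
0.5, so the estimator of delta-d' carries a small positive finite-sample
bias (+0.026 for a true effect of 0.4 at these counts, by exact binomial
computation). The recovery tests compare the pipeline against that exact
expectation rather than the nominal effect; any analysis using per-subject
d' at these trial counts — including the original paradigm — shares the
bias.

## Metrics

Rate curves bin event onsets per subject (1-ms bins by default), normalize
by trial count and bin width, smooth with a centered 100-ms boxcar, and
average across subjects with a normal-theory 95% band. Edge bins whose
smoothing window leaves the analysis span are masked rather than
extrapolated. "Toward the cue" uses only the horizontal displacement sign;
zero-dx events count as neither toward nor away and are excluded from the
proportion's denominator (their count is still reported, and
`n_toward + n_away + n_zero = n_events` always). Trials with no events in
a window are reported but do not enter the per-trial averages. The sliding
window defaults to 400 ms width and 200 ms stride. Density maps mirror
left-cue trials in x so "toward" is always +x, and normalize to unit mass.

## Inference

The hierarchical bootstrap resamples subjects with replacement and carries
all trials of each drawn subject (a subject drawn twice counts twice); a
second-stage trial resample is deliberately not the default. p-values use
the smoothed two-sided null-crossing rule
`2 * min[(1 + #{theta* <= theta0})/(B+1), (1 + #{theta* >= theta0})/(B+1)]`
capped at 1; one-sided variants are available because directional
hypotheses (toward-cue proportion > 0.5) can justify them. For statistics
of the form "mean over subjects of a per-subject summary" a vectorized
path precomputes the per-subject values; it is algebraically identical to
the general path and tested as such. Replicates on which a statistic is
undefined are redrawn, with an error if more than 1% are.

FDR correction is Benjamini-Hochberg, applied within an analysis family
(e.g. the six condition x SOA sensitivity effects). BH is order-preserving
and never deflates a p-value, but it is *not* idempotent in general
([1.0, 0.25] adjusts to [1.0, 0.5], which re-adjusts to [1.0, 1.0]);
constant vectors are its fixed points, and the tests assert exactly these
properties against a from-the-definition implementation.

Null-value conventions for the direction-bias tests: 0.5 for the toward
proportion, 0 deg for signed degrees toward the cue.

Median comparisons use Mood's test without continuity correction (ties
count as not-above the grand median), which makes `phi = sqrt(chi2/N)`
exact.

## Gaze information

Annotators are averaged *before* the distance to ground truth is taken
(the mean annotated locus), not after; the per-annotator alternative is a
one-line change but is not the default. The permutation control reassigns
per-video ground-truth locations across videos (the video/trial is the
permutation unit); for six or fewer videos the permutation group is
enumerated exactly. The synthetic annotation generator gives each
condition a different annotator error SD (intact 100, floating heads 90,
headless bodies 220 px) to reproduce the qualitative ordering —
bodies-only gazers carry far less information about the gaze locus — with
one truth location per video, uniform over the central 60% of the screen.

## Problem sizes and determinism

Default analysis sizes were chosen so the full test suite and the
acceptance script each complete in well under a minute of compute per
heavy stage: 50 traces for detector/oracle equivalence, 200 trials for
injection recovery, 500 cohorts x 1000 resamples for null calibration, 100
cohorts for effect recovery, 1000 trials for direction-bias recovery, and
a 5-subject trace subset inside the end-to-end demonstration (the
behavioral cohort is always the full 30 subjects; bootstrap tests there
use 2000 replicates instead of the 10,000 default). Every stochastic
component draws from an explicit `numpy.random.Generator`; a single seed
reproduces any run bit-identically.

## Known limitations

- The drift model is a pure random walk (no mean reversion, no tremor),
  and blink artifacts are idealized as frozen position + invalid pupil;
  real blink transients produce large spurious velocities that the
  missing-pupil masking only partly suppresses.
- The generator's noise floor is optimistic; detector recovery rates on
  real 1000-Hz video-tracker data will be lower, especially below 0.15 deg.
- The behavioral model has no lapses, no response bias drift, and no
  learning; cueing effects are purely additive in d'.
- Pixel-unit results depend on the configured raster, which is an
  arbitrary default unless the user supplies their display's true
  resolution.
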