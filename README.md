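# gazecue

Analysis pipeline for gaze-cueing experiments that measure how another
person's gaze, head, and body orientation direct a viewer's covert attention.
The package covers the full chain used in such studies: detecting
microsaccades in 1000-Hz eye-tracking streams, quantifying cueing effects on
target-detection behavior with signal detection theory, measuring
microsaccade direction biases toward the cued side, and testing everything
with a hierarchical participant-level bootstrap under false-discovery-rate
control. A first-class synthetic-data generator produces gaze traces with
ground-truth ocular events and signal-detection-governed responses, so every
stage of the pipeline is verifiable without access to human data.

It is intended for visual psychophysicists and oculomotor researchers who
work with Posner-style spatial cueing paradigms — in particular designs with
three gazer conditions (intact person, floating heads, headless bodies), two
cue-to-target delays (SOA 200/500 ms), 50% target presence, and 50% cue
validity.

## Methods at the core

**Microsaccade detection.** Eye velocity is estimated with a moving-average
derivative (5 samples by default). Within each trial a robust velocity scale
is computed per component, `sigma = sqrt(median(v^2) - median(v)^2)`, and
samples exceeding the elliptical criterion
`(v_x/eta_x)^2 + (v_y/eta_y)^2 > 1` with `eta = lambda * sigma`
(`lambda = 6`) for at least 12 ms form an event; events closer than 12 ms
merge. Events with sustained speed above 35 deg/s and peak acceleration
above 9500 deg/s^2 are classified as saccades; events overlapping
missing-pupil spans are blinks. Trials with a blink during the video, or a
fixation excursion beyond 1.5 deg, are excluded.

**Behavioral sensitivity.** Per subject, condition, SOA, and cue validity,
`d' = Phi^-1(H) - Phi^-1(F)` with rates clamped to `[1/(2n), 1 - 1/(2n)]`;
the false-alarm rate is shared within a condition x SOA cell because cue
validity is undefined on target-absent trials. The cueing effect is the
per-subject `delta-d' = d'_valid - d'_invalid` (and the analogous hit-rate
difference), summarized across subjects with Cohen's d.

**Microsaccade direction bias.** Events are aligned to the video or
target-array onset; rate curves are per-subject histograms normalized to Hz
and boxcar-smoothed. An event is "toward the cue" when the sign of its
horizontal displacement matches the cued side; the per-trial toward
proportion and signed degrees toward the cue are scored in a 400-800 ms
post-array window (and in sliding windows).

**Inference.** The hierarchical bootstrap resamples subjects with
replacement and carries all trials of each drawn subject; the two-sided
p-value is the smoothed null-crossing probability
`2 * min[(1 + #{theta* <= 0})/(B+1), (1 + #{theta* >= 0})/(B+1)]`
(10,000 replicates by default). Families of p-values are adjusted with
Benjamini-Hochberg FDR. Amplitude medians are compared with Mood's median
test and the `phi = sqrt(chi2/N)` effect size.

**Gaze information.** For annotated video frames, the estimation error is
the Euclidean distance from the mean annotated gaze locus to the true gazed
location, compared against a baseline that permutes ground-truth locations
across videos. A helper converts a head's angular height to real-world
viewing distance, `D = L / (2 tan(theta/2))` with L = 0.24 m.

## Worked example

Simulate a 30-subject cohort with the default cueing-effect structure
(sustained benefit for intact gazers, transient for isolated heads/bodies)
and bootstrap the sensitivity cueing effect in every condition x SOA cell:

```python
import numpy as np
import gazecue as gc

rng = np.random.default_rng(0)
cfg = gc.BehaviorSimConfig(seed=0)          # 30 subjects, 60 trials/cell
trials = gc.simulate_behavior(cfg, rng=rng, with_timelines=False)
results = gc.bootstrap_cueing_effects(trials, n_boot=2000, rng=rng)
for (cond, soa), r in results.items():
    print(f"{cond:16s} {soa} ms  dD'={r.observed:+.3f}  "
          f"p={r.p_raw:.4f}  p_FDR={r.p_fdr:.4f}")
```

```
floating_heads   200 ms  dD'=+0.477  p=0.0010  p_FDR=0.0020
floating_heads   500 ms  dD'=-0.081  p=0.4368  p_FDR=0.5241
headless_bodies  200 ms  dD'=+0.213  p=0.0240  p_FDR=0.0360
headless_bodies  500 ms  dD'=+0.034  p=0.6837  p_FDR=0.6837
intact           200 ms  dD'=+0.336  p=0.0010  p_FDR=0.0020
intact           500 ms  dD'=+0.508  p=0.0010  p_FDR=0.0020
```

Each line is one design cell: the observed across-subject mean
valid-minus-invalid sensitivity difference, its raw bootstrap p-value, and
the FDR-adjusted value within the six-cell family. With the default effect
structure only the intact condition remains significant at the long SOA —
the sustained-attention signature.

The same workflow is available from the shell via the `gazecue` command
(`simulate`, `detect`, `behavior`, `microsaccades`, `bootstrap`,
`gazeinfo`), each taking `--config` (YAML), `--seed`, and `--out`.

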