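# Methods

This note documents the models, conventions, and numerical choices behind
the package, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic-data tests do and do not show
about real recordings.

## Protocol model

The battery is encoded as 11 conditions: eyes-open (EO) and eyes-closed
(EC) stance controls without VR, a gaze-only 2D control (2D-G), and the
4 x 2 factorial core — environments {2D, 3D, VM, SO} crossed with
{pro, anti} saccade tasks (conditions #4–11). Cycle structures:

| environment | cycle | frames | practice | recorded |
|---|---|---|---|---|
| 2D / 3D | 2.0 s | 1 s fixation, 1 s target/response at ±8° | 10 | 30 |
| SO | 7.5 s | 2.5 s fixation, 2.5 s allocentric view (target at ±2° in the map), 2.5 s response at ±8° | 5 | 15 |
| VM | 10.0 s | 2.5 s fixation, 2.5 s memorise (two distinct symbols at ±2°), 2.5 s fixation, 2.5 s response at ±8° | 5 | 15 |

Posture recording starts at the end of the last practice cycle; EO/EC use
a full 60 s window.

Target sides are displayed an equal number of times overall. The 30-trial
recorded blocks balance exactly; the 15-trial VM/SO blocks balance to
within one, with a seed-determined extra side whose complement goes to the
practice block so the whole 20-trial schedule is exactly balanced. Side
sequences are seeded permutations with at most 3 consecutive equal sides
(anticipation mitigation; configurable). The 2D/3D target stays visible
for the whole response window. Expected direction is the displayed side
for pro tasks and its mirror for anti tasks; in VM/SO the displayed side
is where the cue symbol reappears / where the map places the circle
target, so the same rule applies.

## Synthetic recordings

The simulator defines the study conditions the tests run under:

* **Latency**: shifted log-normal with an 80 ms physiological floor,
  parameterised by mean and SD (defaults 250 / 50 ms for a healthy older
  adult at baseline). Draws that would push the saccade outside the
  response window are redrawn and counted.
* **Saccade waveform**: raised-cosine velocity profile; for amplitude A
  the peak speed is the main-sequence value `vmax (1 - exp(-A/c))`
  (defaults vmax = 500 deg/s, c = 6°, i.e. 368 deg/s at 8°), giving
  duration `T = 2A / v_peak` (~43 ms at 8°). The position trace is
  sigmoidal; direction errors (probability `error_prob`) go to the
  mirrored side.
* **Intrusions**: Poisson-arriving out-and-back excursions of 0.3–0.9°,
  same waveform family — below the 1° saccade threshold by construction.
* **COP**: independent AP/ML Ornstein–Uhlenbeck processes, exactly
  discretised (`x_{k+1} = x_k e^{-θΔ} + σ_∞ sqrt(1 - e^{-2θΔ}) ξ`,
  `σ_∞ = sqrt(D/2θ)`), started from the stationary law. Defaults θ = 1/s,
  D = 8 mm²/s → σ_∞ ≈ 2 mm, a plausible quiet-stance magnitude.
* **Pupil**: base diameter + low-frequency sinusoid + white noise.

Default sample rates are 120 Hz (gaze) and 100 Hz (COP) — conventions, not
device facts. All generators are bit-reproducible under a fixed seed.

What the simulator does **not** emulate: blinks and tracking dropouts by
default (a masked-interval model exists but is off), smooth pursuit,
vergence and head motion, drifts and calibration error in gaze, and
non-stationary or frequency-structured sway. Passing recovery tests on
these recordings therefore demonstrates correctness of the processing
chain, not robustness to every artefact of hardware data; the
invalid-sample path (interpolation of gaps ≤ 100 ms, trial invalidation
beyond) covers the dropout mechanics separately.

The cohort model used by the pipeline layers condition effects on each
subject: anti-saccades add latency (~40 ms) and direction errors, VM/SO
add a cognitive latency cost (~110–150 ms), VM (and to a lesser degree SO)
amplify sway diffusion, and eye closure amplifies it further. These effect
sizes define the demonstration cohort; they are inputs, not findings.

## Saccade detection and scoring

Angular speed is computed from central differences of the horizontal and
vertical gaze angles; each velocity component is smoothed with a centred
5-sample moving average before taking the magnitude. Smoothing the
components rather than the speed keeps the noise floor zero-mean —
smoothing the magnitude leaves a Rayleigh floor that sits near the
threshold once position noise reaches a few tenths of a degree.

Candidate events are maximal runs of smoothed speed ≥ 30 deg/s lasting
≥ 10 ms. Onset and offset are then refined on the *raw* (unsmoothed)
two-point speed, walking outward from the run's raw peak to the nearest
samples below `max(threshold, 0.2 · peak)`; the adaptive refinement level
prevents noise excursions near the base threshold from dragging onsets
into the preceding fixation. Consequences of this convention, measured on
simulated recordings: noise-free onsets land within one sample period of
ground truth; with 0.3° position noise the mean absolute latency error is
~3 ms; the reported amplitude excludes the low-velocity tails (~0.2° at
8°); and the raw-speed peak at 120 Hz under-reads the true peak by ~10–15%
(finite differencing of a ~45 ms pulse), a bias that is constant within a
design and cancels in comparisons.

Events with |horizontal amplitude| < 1° are discarded as non-saccadic.
Scoring uses the first qualifying saccade after the response-frame onset;
onsets < 80 ms are anticipatory (invalid, not errors); corrective saccades
are ignored for latency and peak speed, and an initial wrong-direction
saccade marks the trial incorrect even if corrected. In VM/SO the
gaze-duration rule is authoritative for correctness (dwell in ±3° regions
of interest around the ±8° targets; strict maximum, equal nonzero dwell is
a tie); first-saccade correctness is recorded alongside. Error rate uses
valid trials as the denominator (both conventions are recoverable from the
per-trial scores). Summary SDs use the n−1 denominator.

## Posturography

`sd_ap`/`sd_ml` are sample SDs of the windowed displacement; sway speeds
divide path length by elapsed time (first to last sample). The "envelope
curve" area is interpreted as the convex hull of the trajectory — the
standard outer-envelope convention in stabilometry; the hull is built with
Andrew's monotone chain and measured with the shoelace formula, with
degenerate inputs (< 3 non-collinear points) returning zero and a flag. No
low-pass filtering is applied by default (platform output is assumed
conditioned); an optional zero-phase Butterworth smoother is available.
Units are mm and mm²; cm-declared files are converted at I/O.

## Pupil spectrum

Welch's method on the linearly de-trended series (segments of ~8 s), then
a global rescale so the trapezoidal integral over frequency equals the
de-trended variance. This makes the Parseval check exact by construction
and pins down the normalisation of the band summary (mean density over
0.05–2 Hz by default); absolute values are therefore comparable only
within this convention.

## Statistics

The factorial analysis is an aligned-rank-transform (ART) two-way
repeated-measures ANOVA over conditions #4–11: for each effect
(environment, task, interaction) the response is aligned — cell means and
subject effects stripped, the effect's own estimate restored — midranked
across all observations, and the within-subject F computed on the ranks
with the effect-by-subject interaction as the error term. Constant-level
degeneracies return F = 0, p = 1. A per-factor Friedman test (averaging
over the other factor within subject) is exposed as a cross-check. Under a
null simulation (20 subjects, 4 x 2) the empirical type-I error is ~0.05.

The Wilcoxon signed-rank test drops zero differences by default (Pratt's
method optional), computes the exact two-sided p for up to 25 nonzero
pairs by dynamic programming over the permutation distribution of the
positive-rank sum (midranks doubled to stay integral, so the distribution
is exact under ties), and a tie/zero-corrected normal approximation
beyond. The effect size r = |Z|/sqrt(n) always uses the corrected Z;
magnitude labels use closed-left intervals at 0.1 / 0.3 / 0.5. Pairwise
comparisons follow the design scheme (environments within task, tasks
within environment; the stance controls may be paired freely for the
posture post hoc) and are Holm-adjusted per parameter family by default
(Bonferroni and Benjamini–Hochberg available).

Distributional checks: Levene on absolute deviations from group medians
(Brown–Forsythe) across conditions, Shapiro–Wilk on pooled
within-condition residuals. Spearman matrices use tie-corrected ranks,
two-sided p, and an unadjusted 5% significance flag; constant columns are
masked.

## Problem sizes and determinism

The bundled checks run at deliberate desk scale: schedule balance over
hundreds to a thousand seeds, latency recovery over 60–120 trials,
error-rate recovery over 60–200 30-trial sessions, ANOVA calibration over
1000 null datasets of 20 subjects, and a 20-subject, 11-condition demo
cohort (~25 s on one CPU). All pipeline randomness derives from one seed
via `SeedSequence` spawning; outputs are written with fixed float
formatting and carry a configuration hash, so repeated runs are
byte-identical.

## Known limitations

* Printed peak speeds at 120 Hz carry the finite-difference bias noted
  above; analyses should compare, not interpret, absolute values.
* The exact Wilcoxon path is quadratic in total rank mass and is capped at
  n = 25 nonzero pairs; beyond that the corrected normal approximation is
  used.
* The ART ANOVA assumes a complete within-subject design with one value
  per cell; missing cells are reported, not imputed.
* The AEC convex-hull convention upper-bounds concave "outer envelope"
  variants; values are comparable within the package, not across devices
  with proprietary envelope definitions.
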