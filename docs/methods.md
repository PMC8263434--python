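# Methods

## Problem and data model

Each training session yields one time series per tracked instrument: tip
position (x, y, z) in centimetres at a fixed sample rate (default 100 Hz; the
rate is a manifest field, not an assumption baked into the code), an optional
normalized jaw-aperture channel in [0, 1], and a per-frame inside-the-box
flag. Occluded frames appear as explicit gaps. A session manifest names the
track files, instrument/hand roles and the two anchor-recording windows; a
participant table maps ids to prior laparoscopic case counts, from which the
experience group is derived deterministically (0–9 novice, 10–49
intermediate, ≥50 expert, with the expert subgroup split at 100 cases).

## Smoothing and differentiation

All kinematics derive from a Savitzky–Golay filter: a least-squares local
polynomial fit of order 3 over a 31-frame window, applied per coordinate, with
the same filter producing the 1st–3rd derivatives scaled by the frame period.
Choices the filter specification leaves open:

* **Edge policy.** Frames within half a window (15 frames) of a segment
  boundary lack full filter support and are marked invalid; they are excluded
  from every mean and distribution. Shrinking-window or mirrored-edge variants
  were rejected because edge artifacts inflate jerk, the most
  derivative-sensitive metric. Consequently the averaging `n` counts interior
  frames only.
* **Uniform sampling.** SG differentiation assumes equal spacing; timestamp
  jitter above 1% of the frame period triggers linear resampling to a uniform
  grid at the declared rate.
* **Derivative attenuation.** SG derivatives of band-limited signals carry a
  small low-pass bias that grows with (signal frequency × window duration).
  On a unit circle at ω = 2 rad/s the 2nd-derivative magnitude is biased by
  0.68% at 100 Hz and 0.17% at 200 Hz with the default window. Tests of the
  closed-form circle identities therefore sample at 200 Hz; this is a
  property of the stated filter, not of the implementation.

## Metric definitions

* **Path length** (m): sum of Euclidean steps between consecutive frames whose
  both endpoints are valid and inside the box; computed on *smoothed*
  positions (the trajectory itself is smoothed before analysis). Long
  occlusions split a track into segments and no step is accrued across a
  split, so path length is never fabricated over a gap. Gaps shorter than
  `max_gap` (default 0.2 s) are linearly interpolated and flagged imputed.
* **Velocity/acceleration/jerk** (cm/s, cm/s², cm/s³): mean Euclidean norm of
  the corresponding derivative over valid frames. The per-frame speed ‖d1‖
  used for banding is the same quantity averaged for the velocity metric.
* **Velocity bands**: left-closed right-open intervals with edges 0.5, 2, 5,
  12 cm/s; a frame at exactly 0.5 cm/s is *low*, not idle. Fractions are over
  valid frames and sum to 1.
* **Working axis**: componentwise median of each ~5-s anchor dwell cloud; a
  window whose maximum pairwise spread exceeds 1 cm is rejected as unstable.
  Distance from the target is point-to-segment distance to the axis
  (perpendicular radius inside the extent, nearest-endpoint distance beyond
  it) — a concentric cylinder with capped ends. The same axis abstraction is
  used for all tasks, including those whose physical target is an incised
  line.
* **Zone distribution**: each inter-frame step contributes its length to the
  zone (edges 2 and 4 cm) of its midpoint; per-zone length over total in-box
  length. Midpoint assignment was validated against a crossing-splitting
  oracle (subdividing every step and binning sub-lengths): agreement within
  1% at 100 Hz sampling. The per-zone velocity sub-analysis is frame-count
  based and uses each frame's own position, matching the frame-based band
  metric; a zone the tip never visits is undefined, not zero.
* **Jaw iterations**: a two-threshold state machine (open at ≥0.6, close at
  ≤0.4 of normalized aperture) counts completed open→close cycles; hysteresis
  makes the count immune to chatter, and partial cycles at task end are not
  counted. The thresholds are semantic defaults — the iteration is defined
  behaviourally, not numerically, in the assessment protocol.
* **Insertion episodes**: maximal inside-box runs debounced at 0.5 s (a trocar
  passage cannot be briefer at human speed); outside blips shorter than the
  debounce are treated as tracking glitches and merged.

## Cohort statistics

Metrics are compared across experience groups with the tie-corrected
Kruskal–Wallis test (chi-square approximation, k−1 df); pairwise Mann–Whitney
U tests (exact enumeration when the pooled sample is ≤12 without ties,
tie-corrected normal approximation otherwise) are run only where the
three-group test is significant at α = 0.05. No multiple-testing correction
is applied across metrics, mirroring the raw-p-value reporting convention of
the assessment literature; this is a deliberate caveat.

Significant metrics are normalized by the robust Z-score
z = (X − median)/NIQR with NIQR = IQR × 0.7413 (≡ IQR/1.349), the convention
under which NIQR estimates one standard deviation for normal data; quartiles
use linear interpolation (type-7). PCA is the eigendecomposition of the
covariance of the normalized matrix — robust normalization already equalizes
scales, so no second standardization to correlations is applied (the choice
is switchable by re-standardizing the input). Metrics with zero NIQR are
dropped with a warning; metrics with a non-monotone group trend can be
excluded explicitly (the `exclusions` parameter) without removing them from
the univariate tables. Component signs are fixed so the mean expert score on
PC1 is nonnegative (experts plot right); signs are otherwise arbitrary.

**Calibration notes.** At the cohort composition used throughout (15 experts,
12 intermediates, 18 novices) the true type-I error of the KW chi-square
approximation is ≈0.047 at nominal 0.05; the calibration test estimates the
rate over 10,000 null replicates, enough precision to place it inside
[0.04, 0.06] without Monte-Carlo ambiguity.

## Synthetic cohorts

The simulator generates what the pipeline is meant to measure, with known
ground truth:

* Motion is alternating idle dwells and minimum-jerk point-to-point
  submovements (quintic profile 10s³ − 15s⁴ + 6s⁵), targets drawn near a
  preferred radial distance from the working axis with a random-walk azimuth;
  Gaussian sensor noise (σ = 0.03 cm, typical marker-based tip jitter) is
  added on top. Jaw cycles and insertion episodes are scheduled explicitly.
* Group profiles encode the qualitative skill contrasts: experts pause less
  (idle fraction 0.13 vs 0.30), move at a faster tempo and slightly larger
  reach, hover closer to the axis, cycle the jaws less often, and insert the
  clip applier faster. Task durations are the group-median operative times of
  a real task-1 cohort scaled down tenfold (230/144/96 s) — the package's
  chosen simulation size; all cross-group orderings are preserved.
  Per-participant variation is multiplicative lognormal (σ = 0.15; half that
  on tempo and reach, which are more stable within a skill level than pausing
  behaviour).
* Anchors are embedded as two 5-s dwells 17.5 cm apart, matching the
  axis-calibration procedure.
* Everything is reproducible from one integer seed with no global state.

What the simulator does **not** model: biomechanics of the arm, tissue
interaction, instrument exchanges, camera dropout bursts, or non-stationary
learning within a session. Passing pipeline tests on synthetic cohorts shows
the *computations* are correct and the statistical layer recovers built-in
contrasts; it does not validate the metrics as measures of real surgical
skill.

**Noise floor.** A degenerate all-dwell profile produces zero clean path; with
realistic sensor noise the SG-smoothed trajectory still accrues a noise-floor
path of ≈0.11 m per 30 s (σ = 0.03 cm, 100 Hz) — about 15% of an active
expert profile's path at equal duration. Reducing this below 1% would require
σ ≤ 20 µm, unrealistic for marker-based tip reconstruction; the degenerate
tests assert noise-floor consistency rather than an arbitrary small ratio.

## Problem sizes

Default test and acceptance runs use: single-instrument cohorts at the 18/12/15
composition for replicate studies (100 replicates), two instruments (scissors
and clip applier) for the headline cohort run, 10,000 replicates for null
calibration, and 100 random tracks/schedules for oracle-equivalence and
event-recovery checks.

## Known limitations

* The inside-box flag is trusted when present; the axis-aligned-box fallback
  geometry is not implemented beyond the flag (tracks without a flag count as
  fully inside).
* Operative time is inferred from track spans when the manifest gives no
  explicit start/end.
* The robust-Z/PCA layer requires complete metric columns; sessions with
  undefined metrics simply drop those columns from the multivariate step.
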