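# Methods

This note records the models, algorithms and numerical choices behind
`gaitlidar`, with the reasoning for every decision the problem left open.

## Sensor model and geometry

A planar LiDAR sweeps a 270° window with 2162 beams per revolution at
40 Hz; the beam-to-beam step is `270/2162 ≈ 0.125°`. Beam 0 points at
−135° relative to the sensor heading so that the window is symmetric about
the heading — the natural reading of a "270° window", and the convention
every transform in the package uses. A no-return beam carries a
non-positive sentinel (0.0) and is excluded from all downstream
computation. All internal lengths are metres; gait outputs are reported in
cm, s, steps·min⁻¹ and cm·s⁻¹, matching clinical convention.

Beam coverage of a circular target of diameter *d* at distance *D*
subtends `2·atan((d/2)/D)`; the beam count is the floor of that width over
the angular step (floor reproduces the quoted "around 45 beams on a 10 cm
leg at 1 m"; the unrounded quotient is exposed alongside).

## Synthetic range scans

The simulator exists because the original walking recordings are not
public; it emulates the measurement geometry, not human biomechanics.

**Room and rig.** An 8 m × 6 m living room: four walls in both height
bands, plus shin-height furniture (couch, table, sideboard) kept clear of
the 6.3 m walkway. Three shin-height sensors sit on the perimeter (both
ends of the walkway and mid-side) and one torso-height sensor on the
opposite wall. All distances are configurable; nothing downstream assumes
this layout.

**Walker.** Gait is idealized as alternating single support: stance sites
lie every step length *L* along the path, the stance shin is stationary
for one step period `T = 60/cadence`, and the swing shin travels `2L` with
a half-sine speed profile (zero at lift-off and landing, peak `πL/T`
mid-swing). Foot exchange is instantaneous — the pipeline only needs clear
speed minima and maxima, so double support adds nothing testable. Feet are
offset laterally ±3.5 cm (step width 0.07 m, the centre of the normal
adult range) from the path; the torso moves at the constant mean speed
`L/T` and stops over the final double-stance midpoint. Walks begin
mid-gait (one foot in stance at the path origin, the other mid-swing) so
recordings contain no artificial standing phase. Ground-truth identities
hold exactly by construction: stride = 2L, cycle = 2T, velocity =
L·cadence/60.

**Raycasting.** Every beam is intersected with the static segments of the
sensor's height band, the two shin circles (diameter 0.10 m) for shin
sensors, and an oriented torso rectangle (0.45 m wide, 0.18 m deep) for
the torso sensor; the return is the nearest hit, so occlusion is implicit.
Valid returns get i.i.d. Gaussian range noise (default sd 1 cm, a
realistic figure for these scanners). Static scenes are raycast once and
re-noised per frame, which keeps 2000-frame backgrounds and 12-hour
recordings cheap; multi-hour scenes are produced and consumed in 15-minute
chunks at constant memory.

**Presets.** The four fixed study conditions (30 cm steps at 100 and
120 steps·min⁻¹, 60 cm at 60 and 120), a free walk (65 cm, 105 — mid-range
self-selected gait), a u-turn walk (out along the corridor, a semicircular
arc of radius 0.6 m around a marker, and back), and the long-term static
scene: two pipes of leg diameter 0.25 m apart with a box above, viewed by
all sensors for 12 h (noise sd 5 mm, down-samplable).

## Background model

Per sensor and beam, the empty-room range distribution is Gaussian with
the sample mean and sample sd (ddof 1) over the background sequence
(2000 frames = 50 s at 40 Hz). A later return is foreground when its
two-sided tail probability is below 10⁻⁵ **and** it is shorter than the
background mean: only objects between the sensor and the background are
physical, and the gate keeps dropouts or multipath behind a wall from
being flagged. Numerical choices: an sd floor of 5 mm (noise-free
synthetic input would otherwise make the tail test degenerate), and beams
with under half valid returns are "open" — they have no background
surface, so any valid return on them is foreground. The model is frozen
after fitting; there is no online adaptation.

On pure background the two-sided-plus-gate rule fires at ≈ p/2 per beam;
the test suite bounds the empirical rate at 5·10⁻⁵ to allow estimation
error in the fitted moments.

## Registration

Spatial alignment is the fixed rigid transform per sensor (poses come from
configuration; the mounting is rigid, so there is no auto-calibration).
Temporal alignment anchors frames on the torso sensor (it drives the body
gate) and attaches, per other sensor, the scan with minimal |Δt| within
half a scan period (12.5 ms, boundary inclusive, with a 10⁻¹² s float
guard). Matching is monotone two-pointer — each scan is used at most once
— and is provably the optimal assignment whenever clock jitter is small
against the scan period, which the oracle tests verify against exhaustive
minimum-cost matching.

## Clustering and leg estimation

**Segmentation.** Within each source sensor, points are ordered by bearing
and chained while consecutive gaps stay within the breakpoint threshold
(0.12 m: comfortably above the point spacing on one leg, below typical
inter-leg gaps). Chains — including chains from different sensors, where
no common angular order exists — are merged whenever their closest points
are within the same threshold. Merging on minimum inter-chain distance
(rather than on chain centroids) makes the result *exactly* single-linkage
connected components at the threshold: every within-threshold point pair
either lies inside one chain or links two chains. Clusters under 5 points
are removed as noise.

**Body gate.** The largest torso-sensor cluster is the upper body; shin
points farther than 0.50 m from the body centre are discarded. The
pipeline estimates the body centre as the midpoint of the torso cluster's
extent rather than its centroid: the sensor sees only the near faces of
the torso, so the centroid sits on the body surface, and the flip of the
visible face as the walker passes the sensor would otherwise imprint a
systematic deficit on the walking-velocity estimate. (`find_torso` itself
still returns the plain centroid, which is accurate to within half the
torso depth.)

**Surface-to-centre correction.** Shin returns sample the cylinder surface
facing each sensor. Each point is pushed along its beam by `(π/4)·r`
(r = 0.05 m, half the nominal shin diameter): a beam with impact parameter
*b* reaches the centre plane after a chord depth `sqrt(r²−b²)`, whose mean
over beams uniform in *b* is `πr/4`, so the per-view centroid becomes
unbiased. Pushing by the full radius would overshoot by ≈ 0.2 r and was
rejected.

**Per-frame leg estimates.**

* Two or more clusters: k-means (k = 2) on the pooled points of the two
  largest clusters, seeded at their centroids, ≤ 50 iterations — a
  deterministic refinement with no RNG.
* One cluster whose pairwise extent exceeds 0.18 m (≈ 1.8 leg diameters):
  two legs inside each other's angular shadow. The blob is split by
  k-means seeded at the predicted leg positions. This case covers a
  quarter to a half of all swing frames at short step lengths, and
  treating it as "one leg plus a ghost" is what destroys tracking if
  omitted.
* One compact cluster: its centroid is the visible leg; the other leg runs
  an SIR particle filter (500 particles). Prediction moves each particle
  by the previous upper-body velocity times a per-particle uniform draw
  from [0.5, 2.0] plus Gaussian process noise (sd 3 cm); weights come from
  a Gaussian likelihood (sd 3 cm) of the distance to the nearest gated
  point, but only when some point lies within a 0.15 m measurement gate of
  the particle cloud — during a merge the cluster genuinely contains the
  occluded leg's returns, while during a true occlusion the visible leg's
  points must not capture the filter. Systematic resampling runs every
  frame; the estimate is the weighted particle mean, and the particle set
  rides along in the estimate so occlusions can span frames.
* No clusters: both legs filtered, prior-only by default.

Tracking initializes at the first frame with two separable clusters;
earlier frames are unresolved.

**Association.** Estimates are matched to legs by minimum-total-distance
(optimal for 2×2) against *constant-velocity predictions* anchored at each
leg's last measured position — filter estimates never update the anchor,
the velocity is a smoothed difference of measured positions, and the
extrapolation horizon is capped at 0.3 s. Raw last-position matching fails
systematically at merge exit (the blob centroid migrates forward while the
filter lags, so the identities cross); anchoring on measured history is
what keeps them straight.

## Left/right labelling

The walking direction is the torso displacement over the first 0.5 s of
resolved frames, grown until it exceeds 5 cm. The leg whose body-referenced
position lies counter-clockwise of the direction (positive z of the 2-D
cross product) is the anatomical left; with the direction reversed the
labels swap, and a collinear configuration defers the decision to the next
frame. Labels then propagate along the identity-consistent estimate
sequence. "Left" means left of the direction of travel.

## Gait analysis

Per-leg speed is the centred finite difference of the track, smoothed by a
centred 9-sample moving average (225 ms — below half the shortest step
time among the study conditions, so stance minima survive; edges use the
available partial window).

Stance detection: samples below a ceiling of 25 % of the profile's 90th
percentile form candidate stance regions (the percentile makes the ceiling
scale-free across slow and fast walks). Regions not separated by a genuine
swing — the speed between them never reaching 50 % of the same percentile
— are unioned: estimation wobble mid-stance (the other leg passing through
the merged-blob case) otherwise splits one stance into two events and
doubles cadence. The stance *position* is taken at the region's speed
minimum (the foot is stationary there); the stance *instant* is the middle
of the region expanded out to the surrounding genuine-swing boundaries,
which stays unbiased when wobble clips one side. The swing peak between
consecutive stances is the interval's speed maximum.

Parameters from the merged, time-sorted stance sequence:

* stride length / cycle time — chord distance / time between consecutive
  stance events of the same leg;
* step length / step time — between a stance event and the preceding
  opposite-leg event; the length is the projection onto the local line of
  progression (the surrounding same-leg stride vector), which is what a
  pressure walkway reports. The raw chord also contains the lateral step
  width and would inflate a 30 cm step by ≈ 0.8 cm, breaking the
  stride ≈ 2·step identity;
* cadence — `60 · steps / (last − first stance instant)`, one value per
  walk;
* velocity — torso path length over the same span, from the smoothed torso
  track sampled at the stance instants (chords between stance-time
  samples; no straight-line assumption, so u-turns work).

The pipeline drops stance events whose stance phase touches the recording
boundary before computing parameters: a truncated stance has a biased
instant, and one inward-shifted endpoint is worth ±2 steps·min⁻¹ of
cadence. The library function leaves trimming off by default so that
worked examples on hand-built event series behave literally.

## Long-term drift

Static-scene positions are estimated per sensor individually (no pooling —
the point is to assess each sensor), trimmed 15 min at both ends, bucketed
into 15-min windows, and summarized by median and quartiles per
coordinate. Drift is the least-squares slope of window medians over time
in mm/h with a 95 % t-interval; "no drift" means the interval contains
zero. The median pipeline is shift-equivariant, and on the synthetic 12 h
scene (noise sd 5 mm at 1 Hz) window medians stay within ±2.5 mm of the
noise-free reference estimate — the reference is the estimate, not the
physical pipe centre, since a surface-sampling offset of a few cm is
constant in time and irrelevant to drift.

## Device-comparison statistics

Paired two-sided t-tests with Bonferroni adjustment (`p_adj = min(1, m·p)`),
the mean difference with a t-interval, and RMSE; Pearson r plus a
regression-based R² (B regressed on A — deliberately not r², so outliers
can pull the two apart); the intraclass correlation from the two-way ANOVA
mean squares in both single-measure forms, consistency
`(MS_R − MS_E)/(MS_R + (k−1)MS_E)` and agreement (adding the
`(k/n)(MS_C − MS_E)` term), reported side by side because the two
conventions are easy to conflate; and Bland–Altman bias with
`bias ± 1.96·sd` limits, returned as data (plotting is the caller's
concern). Zero-variance differences are reported as exact equality rather
than a t-statistic.

The a-priori sample size solves the two-sided paired-t power problem by
noncentral-t iteration (power = `P(|T_{df,nc}| > t_crit)` with
`nc = d√n`), with the normal-approximation closed form
`((z_{1−α/2}+z_{1−β})/d)²` as a cross-check; at d = 0.3, α = 0.01,
power = 0.99 both give ≈ 268 observations, i.e. 20 participants at 14
paired observations each.

## Problem sizes and determinism

Defaults throughout are the operating constants above; every stochastic
component (simulation noise, particle filter) draws from a generator
seeded in configuration, so fixed seeds give bit-identical runs. The test
suite simulates full-length walks (≈ 5–13 s, 200–550 frames at 40 Hz) for
each preset once per session, a 2000-frame background, and the 12 h static
scene down-sampled to 1 Hz — sizes chosen so the whole suite exercises the
complete method at realistic scale.

## What the synthetic tests do and do not show

Passing recovery tests demonstrates that the pipeline correctly inverts
the measurement geometry it models: surface sampling, occlusion between
legs, multi-sensor overlay, noise. Real data add clothing reflectivity,
foot pitch and double support, non-instantaneous weight transfer,
asymmetric and variable gait, clock drift between sensors, and multipath —
none of which the simulator emulates, so agreement statistics on synthetic
walks say nothing about clinical accuracy. Known limitations: a single
walker only (the clustering assumes exactly two shins inside the body
gate); no re-identification after a track loss longer than the predictor
horizon (tracking re-initializes); swing/stance time and double-support
metrics are out of scope; cluster-level left/right identity during the
1–3 frames where the legs physically coincide is undefined in principle.
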