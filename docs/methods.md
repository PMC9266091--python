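# Methods

`frailsense` is a desk-scale re-implementation of the sensing and perception
pipeline of a walking-support robot used for frailty screening. The robot
observes an older adult during an assisted 10 m walk with three contactless
sensor groups — a rear-facing 2-D laser range finder at shank height, an
RGB-D camera viewing the upper body, and 16 force sensors in the handle —
while wearable inertial units (both feet and the sternum) provide the
clinical reference route. This note describes the models, the estimators,
the synthetic data that stands in for the unavailable recordings, and the
numerical choices behind both.

## 1. Gait model and event definitions

A *stride* is one full gait cycle of one foot, delimited here by successive
toe-offs (TO); the *swing* phase runs from TO to the next heel-strike (HS)
of the same foot and *stance* from HS to the next TO. Per foot, nine
features summarise the walk (suffix `R`/`L`):

| acronym | meaning | unit |
|---|---|---|
| `GT` | gait time, first to last detected event | s |
| `GSTRD` | number of strides (= number of TOs) | – |
| `GSTRDL` | stride length | m |
| `GSTRDT`, `GSTRDT_SD` | stride time mean, SD | s |
| `GSWT`, `GSWT_SD` | swing time mean, SD | s |
| `GSTT`, `GSTT_SD` | stance time mean, SD | s |

Stride durations are TO→TO differences, so `GSTRD` TOs give
`GSTRD − 1` duration samples; with fewer than two samples an SD of 0 is
reported.

### Inertial route

The sagittal-plane foot angular rate (gyroscope axis perpendicular to the
direction of progression) is filtered with a fourth-order low-pass
Butterworth at 5 Hz, applied forward–backward (`filtfilt`) so event
timestamps carry no filter lag; the effective magnitude response is the
squared one-pass response with bilinear prewarping,
`|H(f)|² = (1 + (tan(πf/fs)/tan(πf_c/fs))^8)^{-1}`.

Events follow the canonical trough–peak–trough template of foot-mounted
gyros: mid-swing positive peaks are detected first (prominence ≥ 30 % of
the signal IQR, floored at 10 % of the signal span because a
stance-dominated recording has an IQR near the noise floor; height ≥ 30 %
of the signal maximum, because a flat stance baseline flanked by two deep
troughs inherits their topographic prominence while staying near zero).
Each peak's TO is the nearest preceding negative trough and its HS the
nearest following one; overlapping cycles that would share a trough are
dropped. A `sign` flag accommodates the mirrored mounting convention.
Stride length on this route uses the protocol's known distance:
`GSTRDL = 10 m / GSTRD`.

### Laser route

Each 10 Hz scan (240°, 0.36° steps, ≤ 4 m) is converted to Cartesian
points; points inside the leg window (x ∈ (0.2, 1.5] m along the walking
direction, |y| ≤ 0.5 m) are clustered by splitting the angularly ordered
sequence at Euclidean gaps > 0.15 m. Frames without exactly two clusters
are dropped — no interpolation — and left/right labels are assigned by
lateral sign on the first accepted frame, then maintained by
nearest-centroid association. Only the x coordinate (robot at x = 0) is
analysed: swing moves the foot toward the robot, stance away, so local
maxima of x are TOs and local minima HSs (prominence ≥ 25 % of the track's
span; ties break toward the earlier sample).

Because the track is close to piecewise-linear between events and the
swing and stance slopes differ, the raw 10 Hz argmax is biased ~0.03 s
toward the shallow-slope side; event times are therefore refined to
sub-scan resolution by intersecting the two flanking linear segments
(exact for a piecewise-linear track, clamped to the neighbouring samples).
Laser stride length is the length of the x-curve between consecutive TOs,
computed as the total variation of x over the interval — x–time arc length
would mix units — and averaged over strides.

### Torso sway

The sternum gyroscope's yaw rate is filtered as above and integrated
(trapezoidal) between consecutive heel-strikes of either foot; `THETAI` is
the mean over steps of the peak absolute excursion, `THETAI_SD` the SD.
Sensor bias is estimated as the mean over the whole recording and removed
once: left and right sway alternate in sign, so full steps cancel, whereas
per-step mean removal would annihilate the very oscillation being measured.

## 2. Posture features

Four BODY_25 keypoints are used (nose 0, neck 1, right shoulder 2, left
shoulder 5; image origin top-left, y down, 0-based pixels). Per retained
frame: the shoulder-line slope `m = Δy/Δx` and inclination
`θ = atan2(Δy, Δx)` folded into (−90°, 90°] (vertical line → θ = 90°, slope
flagged infinite); the nose–neck pixel distance `DIS`; nose and neck
displacements between consecutive retained frames; and the neck depth. The
13 aggregates are means and SDs of `m`, `θ`, `DIS`, the two displacement
series, plus `Zmin`, `Zmax` and `ZRMSE` of the depth series. Two
conventions are deliberate and configurable:

* `THETA` aggregates |θ| — the inclination magnitude irrespective of lean
  side (a signed mean is available via `theta_absolute=False`);
* `ZRMSE` is the RMS deviation about the series mean, the only reference
  computable without extrinsic calibration.

When several people are detected, the main user is tracked from their
initial pose (highest-confidence person of the first frame): each frame
keeps the person nearest in mean keypoint distance to the last accepted
pose, and frames are dropped when that distance exceeds 150 px or the mean
keypoint confidence falls below 0.3.

## 3. Handgrip

The 16 handle channels (0–7 right hand, 8–15 left) are summed per hand,
smoothed with a centred 0.1 s moving mean, and `MFR`/`MFL` are the global
maxima of the smoothed profiles. The "peak" is read on the summed profile
rather than its derivative, matching how a dynamometer maximum is reported.

## 4. Cross-modality statistics

Feature-by-feature, the two gait tables (laser vs IMU, subjects as rows)
are compared with: a one-sample Kolmogorov–Smirnov test against a normal
fitted to each sample (motivating the non-parametric route), a two-sided
Mann–Whitney U test, OLS of one route on the other (R, slope-test p, RMSE
and MAE of residuals), and Spearman's ρ. For group sizes ≤ 8 the
Mann–Whitney p is exact: the permutation distribution of U is enumerated
over all C(n₁+n₂, n₁) rank assignments with midranks, so ties are handled
exactly and two identical samples give p = 1. Larger samples use the
tie-corrected normal approximation. Significance is flagged at α = 0.05
with no multiple-testing correction (flags are descriptive, not
confirmatory).

## 5. Profiling and 2-D embedding

Each subject's 24-feature profile concatenates the 9 right-foot laser gait
features, the 13 posture features and the two grip maxima, in that fixed
order. Because units mix seconds, pixels and newtons, columns are z-scored
(population SD; constant columns map to 0) before any distance is taken —
raw Euclidean distances would be meaningless. Two reductions are run:

* **exact t-SNE** (Euclidean metric, PCA initialisation, default
  perplexity 3 — it must stay below the cohort size of 10), deterministic
  for a fixed seed;
* **Sammon non-classical MDS**, minimising
  `E = (Σ δᵢⱼ)⁻¹ Σ (δᵢⱼ − dᵢⱼ)²/δᵢⱼ` over planar configurations, where δ
  are input-space and d embedded distances. The optimiser starts from the
  classical-scaling (PCoA) configuration and descends the analytic stress
  gradient with a backtracking line search that never accepts an increase,
  so the stress sequence is non-increasing by construction; iteration stops
  at relative improvement ≤ 1e-12 or 500 iterations (best-so-far returned
  with a warning). Coincident inputs are jittered by 1e-9 in the distance
  domain to keep denominators finite. Stress is reported ×100 as a
  percentage.

## 6. Synthetic data generator

No recordings are distributable, so a generator plants one ground truth
per subject — stride schedule, swing/stance split, torso sway amplitude,
posture geometry, grip peaks — and renders all four raw streams from it.
Every parameter below was fixed from the emulated population's published
summary statistics or from sensor data sheets, once, at design time.

**Schedule.** Right-foot stride durations are drawn from a truncated
normal (defaults 2.32 ± 0.53 s, floor 0.2 s). The left foot steps at
`phase_offset` (default 0.5, the asymmetry knob) of the concurrent right
stride plus ~20 ms jitter — deriving one foot from the other keeps the
feet strictly alternating at ≈ half-stride offset, as in real gait;
independent draws at this stride variability would let the feet drift past
each other within a 10 m walk. Swing time is tied to the subject's mean
stride (`swing_fraction` × mean, default 0.19) with its own 0.08 s jitter
and a physiological floor of 0.25 s: swing varies far less than stride
time in humans, and sub-0.2 s swings would vanish under the 5 Hz filter.

**Laser.** Legs are 0.12 m cylinders at ±0.15 m lateral offset whose
robot-relative x is piecewise-linear between events: maximal at TO,
minimal at HS. The per-stride amplitude is half the per-stride ground
distance, so the total variation of x over a stride equals the planted
stride length and the two routes' stride lengths are commensurable. (On
the real robot the relative-motion amplitude also depends on the
controller's velocity profile, which is why the emulation should not be
read as asserting equality of the two stride-length definitions in the
field.) A 1 s lead-in ramp and trailing plateau make the first and last TO
detectable extrema. Beam returns are exact ray–cylinder intersections on
the 667-beam grid with Gaussian range noise (default 5 mm); optional
dropout deletes one leg's returns for a whole frame.

**IMU.** Foot gyro cycles are sums of Gaussian lobes: a +200 °/s mid-swing
lobe (σ = swing/6, floored at 25 ms) and −100 °/s troughs (σ = 40 ms)
exactly at TO and HS. The sternum yaw rate is a per-step half-sine of
alternating sign whose integral per step equals the planted sway. Gyro
noise defaults to 0.2 °/s (a mid-grade wearable IMU at 100 Hz);
accelerometer channels carry gravity plus noise and are unused.

**Pose.** 30 fps frames with constant planted shoulder inclination and
nose–neck distance, a common-mode lateral sway sinusoid, neck depth
oscillating between the planted extremes, per-keypoint Gaussian pixel
noise (default 0.5 px) and confidences in [0.7, 1]; an optional distractor
person sits 300 px away with confidences in [0.35, 0.6], and optional
dropout empties frames.

**Force.** Ramp–hold–release envelope with a 5 s hold; each hand's eight
channels share the planted total by a fixed Dirichlet split. Noise is
proportional to the reading (%-of-load accuracy, as for piezoresistive
film sensors), anchored so that `force_noise_n` (default 1 N) is the SD of
the summed profile at a 76.5 N reference plateau.

**Cohorts.** `sample_cohort` draws per-subject parameters around the
population values: healthy subjects at stride 2.2 ± 0.35 s, ~19 strides
per 10 m, sway ~1.1°, grip ~85 ± 25 N; walker-dependent subjects (the last
`n_walker` of the cohort) at stride 3.4 ± 0.35 s, ~29 strides, sway ~3.5°,
grip ~35 ± 10 N, higher shoulder inclination. "Low-noise" conditions for
recovery checks (`GaitGroundTruth.low_noise()`) set laser 2 mm, gyro
0.1 °/s, pose 0.2 px, force 0.3 N — the favourable end of the emulated
sensors' ranges.

**What the generator does not emulate.** Real limb kinematics (double
support, foot pitch during roll-over), camera projection (keypoints are
planted directly, never rendered), controller-dependent robot velocity,
soft-tissue and mounting artefacts in the IMUs, and cross-sensor clock
skew (all streams share one clock). Passing tests therefore demonstrate
that the estimators are correct for signals with the documented event
structure and noise, not that they are robust to every artefact of field
recordings.

## 7. Numerical and design choices

* Zero-phase filtering needs > 15 samples at order 4; shorter signals are
  rejected explicitly.
* Laser frames with < 50 % two-centroid retention warn; zero retention is
  an error. Fewer than two detected strides warns and yields no features.
* Degenerate statistics are flagged rather than silently computed:
  zero-variance samples have no defined KS normality p (NaN + warning),
  constant x rejects the regression, constant input makes Spearman NaN.
* Feature tables carry the plain feature acronyms as CSV headers; units
  live in this note (gait in seconds/metres, image features in pixels,
  depth in millimetres, angles in degrees, forces in newtons).
* Laser stream files use ISO-8601 timestamps at nanosecond resolution; IMU
  and force files use float seconds from start. Both round-trip within
  1e-9.
* Problem sizes in the test-bench and `scripts/acceptance.py`: 20 cohorts
  of 10 subjects (2 walker-dependent) per condition set — the size at
  which the Monte-Carlo rates of interest (agreement and separation
  fractions) stabilise while a full run stays comfortably interactive.

## 8. Known limitations

* The exact Mann–Whitney path enumerates C(n₁+n₂, n₁) assignments and is
  capped at 8 per group (12 870 assignments); beyond that the asymptotic
  approximation is used even though n ≈ 10 is still small.
* Sammon mapping is non-convex; the PCoA start is deterministic but can
  settle in a local minimum for adversarial configurations (the 3-point
  oracle tests bound this on small instances).
* t-SNE at n = 10 with perplexity 3 is a visualisation aid, not a metric
  embedding; no stress is defined for it.
* Pixel-domain posture features are not converted to metric units: the
  camera's mounting height and intrinsics are not part of the data model.
* `GSTRDL` on the laser route inherits the generator's amplitude
  convention (see §6); on real recordings the two routes' stride lengths
  measure different physical quantities and should be compared by
  regression, not identity.
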