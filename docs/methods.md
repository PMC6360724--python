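# Methods

This note records the model, the numerical choices, and the limits of
what the test suite demonstrates.

## Kinematic model

**Technical frames.** Each tracked segment (pelvis, thigh, shank/tibia,
hindfoot, midfoot, forefoot, first metatarsal) is represented by a marker
cluster of at least three non-collinear markers. The cluster's reference
geometry is its mean marker configuration in the natural double-leg
stance trial, so the stance pose of every cluster is the identity and the
pose in any other frame is the proper rigid transform minimising the sum
of squared marker distances (SVD solution; if the raw solution is a
reflection the smallest singular direction is flipped). Marker weights
are uniform. Pose estimation is per frame; no temporal coupling is
imposed beyond the trajectory filter.

**CAST.** Calibration-only points — malleoli (LMAL, MMAL), heel offset
(CALe), first metatarsal head (MT1), femoral epicondyles (LEP, MEP) — are
expressed once in their owning cluster's technical frame and
reconstructed rigidly in every trial. On noise-free rigid motion the
chain is exact to machine precision (tested to 1e-9 mm).

**Anatomical frames.** The multi-segment model the study protocol follows
does not print per-segment axis recipes, so this package declares
explicit ones and isolates them in one construction function
(`footmodel.calibrate_stance`) so alternatives can be swapped:

| frame | origin | anterior axis (projected horizontal in stance) |
|---|---|---|
| tibia | mid-malleoli | perpendicular to the LMAL→MMAL line |
| hindfoot | CAL | CAL→CALe |
| midfoot | mid(MFM, CUB) | toward MFD |
| forefoot | MTB2 | MTB2→MT2 |
| first metatarsal | MT1 | MTB1→MT1 |
| whole foot | CALe | CALe→FTML, FTML = mid(MT1, MT5) |
| thigh / shank (knee) | knee joint centre (mid-epicondyles) | perpendicular to the SARA flexion axis |

All stance verticals equal the laboratory up-axis by construction; the
constant technical-to-anatomical rotation is then carried by the cluster
(CAST applied to frames), so angles are absolute rather than zeroed
offsets. One structural consequence: **frontal and sagittal components
are zero-referenced to the calibration stance** (the horizontal
projection discards them), while transverse components retain the
subject's stance geometry. Condition *differences* — the study's effect
measures — are unaffected.

The whole-foot frame spans deformable anatomy, so it is rebuilt per frame
from the reconstructed CALe and FTML with the hindfoot vertical as
transverse reference, then corrected by a constant stance snapshot. When
the foot moves rigidly this equals cluster carriage exactly.

**Angles.** Joint rotation = intrinsic y–x–z Cardan decomposition of
`R_parentᵀ R_child` (sagittal, frontal, transverse), the dominant
convention for ankle-complex joints; the sequence is configurable per
call. Frames are built identically for both limbs (y to the laboratory
left), and a per-side sign (`jointkin.side_sign`) maps the raw frontal
and transverse components to side-independent clinical conventions:
eversion, abduction, external rotation positive. Decompositions within
5° of gimbal lock raise a warning; the foot-model angles stay far from
it. The first-MTPJ angle is a projection angle, not a Cardan component:
MT1→HAL and the metatarsal anterior axis are projected into the plane
normal to the metatarsal vertical axis and the signed angle is reported
with lateral deviation positive.

## Signal processing

Sauté (dynamic) marker data are filtered with a zero-phase Butterworth
filter: two passes (forward/backward) of an order-2 design, net order 4,
no cutoff correction for the dual pass, odd-reflection padding of 3x the
net order. Static trials are averaged unfiltered. The pipeline default
cutoff is 26 Hz; `signalproc.residual_analysis` implements the
residual-analysis selection (grid default 1–50 Hz, straight-line fit to
the upper half of the grid, intercept at 0 Hz as the noise estimate).
The selection rule accepts the smallest cutoff whose residual falls below
`max(intercept, 0.02 x centred-signal RMS)`: the relative floor is needed
because a noise-free signal has a ~zero intercept that its power-law
residual decay never crosses.

## Functional joint calibration

SCoRE solves the stacked linear system `R_p c_p + t_p = R_c c_c + t_c`
over all frames for the centre pair (c_p, c_c). A hinge-only record
leaves the centre undetermined along the axis; the minimum-norm solution
(a point on the axis) is returned, and a conditioning error is raised
only when two or more directions are unobservable (e.g. pure
translation). SARA takes the right singular vector of the smallest
singular value of the same 3F x 6 matrix without the translation terms;
ball-like motion (two comparable small singular values, ratio < 4) raises
an ambiguity warning. The knee angle uses the epicondyle-midpoint centre
(lunge trial) and orients the thigh/shank mediolateral axes along the
SARA axis, each combined with the stance vertical.

## Event extraction

Demi-plié = per-cycle local minimum of the pelvis-cluster centroid
height. Minima must be separated by at least 0.4 beat periods of the
configured tempo (95 bpm default → 0.253 s) and exceed 10% of the
series' peak-to-peak range in prominence — without the prominence floor,
noise ripple on the nearly flat tops between jumps registers as extra
cycles. Plateau ties resolve to the earliest frame; a flat signal is an
error, not an empty result. "Consistent" jumps are operationalised as
the consecutive triplet minimising the coefficient of variation of
peak-to-trough excursion (ties → earliest), and each variable is averaged
over the three selected frames.

## Measures and statistics

Navicular drop = natural-stance navicular height − condition height
(negative = the navicular rose); natural stance is definitionally zero
and is reported only for the other conditions. The hallux-valgus scheme
has a printed gap between "mild" (15–20) and "moderate" (21–39); values
in (20, 21) are graded mild. The navicular "7 to 13 mm" band is treated
as the closed interval [7, 13]. Group summaries use SE = sd/√n and
normal-approximation 95% CIs (multiplier 1.96).

The repeated-measures ANOVA computes the within-subject F from explicit
sums of squares; Greenhouse–Geisser ε̂ = (tr S̃)² / ((k−1) tr S̃²) on the
double-centred condition covariance, clipped to [1/(k−1), 1] (exactly 1
at k = 2); the corrected p uses F at (ε̂(k−1), ε̂(k−1)(n−1)) df. Pairwise
comparisons are two-sided paired t-tests with Bonferroni factor
k(k−1)/2, capped at 1. Stepwise regression is SPSS-style forward entry
(p ≤ 0.05) with backward removal (p > 0.10), iterated to a fixed point
with a cycle guard; with both thresholds at 1 it reduces to full OLS.
Pearson p-values use t = r√((n−2)/(1−r²)). scipy supplies only
distribution functions; pingouin serves as an independent oracle in the
tests.

## Synthetic data generator

The generator is a rigid forward-kinematic chain
pelvis–thigh–shank–hindfoot–midfoot–forefoot–first metatarsal–hallux.
Standing and jumping trials are rooted at the planted hindfoot (ankle
fixed, chain composed upward and downward), calibration and seated trials
at the pelvis. Joint rotations are composed in the same y–x–z convention
the analysis decomposes, from clinical waveforms; static conditions hold
constant offsets and sautés modulate each angle with
w(t) = (1 − cos 2πft)/2 at the configured tempo (95 bpm, 10 cycles,
250 Hz default), so prescribed condition values are attained exactly at
the demi-plié instants. Pelvis height falls with the knee-flexion
waveform (default amplitude 50°, ~145 mm excursion); per-cycle knee
amplitude jitter (3% SD) makes the excursions realistically inconsistent
for triplet selection. Default static offsets are the published group
means of the four study conditions; hindfoot (ankle-complex) abduction
and knee external rotation, which the published table does not list, are
set to plausible turnout contributions. Instrument error is i.i.d.
Gaussian noise per marker coordinate (default 0.5 mm in noisy scenarios).

Arch lowering cannot be expressed by rigid segments (a planted-foot chain
barely changes navicular height), so navicular drop is generated as an
explicit prescribed vertical displacement of the NAV marker — a
soft-tissue deformation degree of freedom. NAV is therefore an anatomical
marker outside the midfoot tracking cluster (MFM, CUB, MFD).

Default geometry is a plausible adult right leg (mirrored for left),
chosen so every anatomical frame is exactly axis-aligned in the neutral
pose and the hallux marker lies on the metatarsal axis — this makes
neutral-pose angles exactly zero, giving clean recovery oracles. Thigh
and shank triads are sized like real instrumented cluster plates (~80 mm
marker spread); foot clusters are anatomically small. The geometry is
declared test geometry, not an anthropometric claim.

**What the generator does not emulate:** soft-tissue artifact (an
optional hook exists but is off by default — nothing in the protocol
calibrates it), flight phases (the foot stays planted through the jump
cycle; demi-plié timing and extraction are unaffected), marker occlusion
patterns, and non-white instrument noise. Passing recovery tests
therefore demonstrate correctness of the estimation chain under the
stated noise model, not robustness to skin-motion artifact.

## Problem sizes and numerical notes

Static trials are 1 s (250 frames), squat/circumduction 8 s, sautés
10 cycles (~6.3 s); recovery tests use one clean and one noisy subject,
the functional-calibration checks 500 frames, Monte-Carlo pose checks
1000 transforms, and the ANOVA null calibration 2000 simulated cohorts of
18 x 4. Gaps are represented by explicit flags and rejected (never
interpolated) when a required marker is affected. Pose estimation raises
on collinear clusters (second singular value < 1e-9 of the first).
Determinism: every stochastic path takes a seed; per-trial noise streams
derive from (seed, trial-label index) so trials are independently
reproducible.

## Known limitations

* The first-MTPJ transverse angle is noise-limited by the small
  first-metatarsal cluster: under 0.5 mm i.i.d. marker noise its waveform
  RMS error after 26 Hz filtering is ~0.9°, roughly twice that of the
  segment-to-segment angles, because the cluster's transverse orientation
  noise enters twice with the same sign (axis direction and reconstructed
  MT1 vertex). Demi-plié-extracted values inherit about 1/√3 of this.
* Frontal-plane angles are referenced to the calibration stance (see
  above); absolute frontal offsets in the natural posture are not
  recoverable under these frame recipes.
* Hip angles, kinetics, sagittal-plane reporting, and gap filling are out
  of scope.
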