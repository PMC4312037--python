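# Methods

This note documents the models behind `murine-dce-quant`: what the
synthetic data emulate, the quantification procedures and their tunable
parameters, the numerical choices made where the design was open, and what
the passing tests do — and do not — demonstrate about real data.

## The digital heart phantom

**Geometry.** The LV cavity is an axis-aligned ellipsoid (long axis = z,
apex at −z), default diastolic semiaxes (2.0, 2.0, 3.3) mm, giving an
end-diastolic volume of 55.3 mm³ — a realistic adult-mouse LV. The
myocardium is the set of voxels within `wall_thickness_mm` (default
1.0 mm) of the voxelized cavity surface, computed with a Euclidean
distance transform. A uniform-thickness *parallel* shell was chosen over a
second, confocal ellipsoid because parallel surfaces of ellipsoids are not
ellipsoids: with an EDT shell the ground-truth wall is geometrically the
same object that `segment_myocardium` reconstructs by dilating the
segmented blood pool, so wall-band mismatch does not contaminate the
percent-infarct denominator. The cavity itself stays analytic, preserving
the `(4/3)πabc` volume oracle (voxel counts agree with it to ≈0.04% at
77 µm spacing).

Systole is an isotropic contraction of the diastolic cavity:
`PhantomSpec.from_ef` sets the systolic semiaxes to
`dia · (1 − EF)^{1/3}`, so the analytic ejection fraction equals the
requested value exactly.

**Infarct.** The LAD-territory infarct is the part of the wall inside an
azimuthal wedge that extends a fraction (default 0.75) of the heart's
length up from the apex. For a prolate (a = b) heart, equal azimuth is
equal volume, so `azimuth_span_for_infarct_fraction` converts a target
infarct load into a wedge span using a coarse (0.12 mm) voxelization of
the shell's apical volume fraction; realized loads land within ~1–2% of
target, and all recovery tests compare against the *realized* label
counts, not the target.

**Contrast and noise.** Voxels take their tissue's washout HU plus i.i.d.
Gaussian noise (default SD 30 HU; the printed ± figures in the source
study are between-subject spreads, not voxel noise, so voxel noise is a
generator choice). Background soft tissue sits at 50 HU. Washout is
mono-exponential — the standard single-compartment tracer form, and the
unique two-parameter curve through the two measured time points (13 and
30 min). Calibration is exact through both points by construction. The
intravascular (lipid-emulsion) agent used for the diastole/systole pair
was never tabulated in HU, so the generator's blood-pool model is its own:
blood 500 HU with negligible clearance (λ = 0.002 /min), non-enhancing
myocardium and infarct at 120 HU. One acquisition-time convention: the
first/second Iohexol acquisitions are taken at 13 and 30 min throughout
(the study's text is internally inconsistent about the second point;
its figure states 13 and 30).

**Motion streaks.** Suboptimal gating shows up as bright streaks crossing
the thorax. `add_motion_streaks` adds in-plane lines through the heart
with super-Gaussian (exponent-4) cross-sections ~2 voxels wide and a
limited (~0.8 mm) axial footprint, amplitude 220 HU × severity, 15 streaks
by default. The profile matters: hard-edged streaks saturate the
delayed-enhancement threshold locally and make the infarct over-counted,
mimicking the study's motion subject (CT overestimated by ~11 points);
soft, wide streaks instead fatten the whole myocardial HU distribution,
inflate the robust threshold and *under*-count. At the defaults the CT
estimate is displaced upward by ~5–8 points on a ~32% infarct.

**TTC rendering.** The diastolic label field is cut into short-axis slabs
(default 1 mm) and each slab's two faces are rendered at `pixel_size_mm`
(default 0.02 mm) by nearest-neighbour sampling: viable myocardium
RGB (180, 40, 50), infarct (235, 190, 190), background and open cavity
white, with per-channel Gaussian jitter (SD 10 of 255). These constants
are exported so the histology thresholds can be tested against them. True
per-face areas are recorded from the same sampled plane.

**Cohort.** `simulate_cohort` draws IR subjects with EF ~ N(0.36, 0.11)
truncated to (0.05, 0.95) and infarct load ~ N(0.32, 0.08) truncated to
(0, 0.6), and controls with EF ~ N(0.59, 0.07) and no infarct — the group
structure of the source cohort (its printed control spread of "0.7" is
read as the evident misprint of 0.07).

## Gating simulation

Respiration is a raised-cosine inhalation/exhalation bump followed by an
exact-zero end-exhalation plateau occupying `plateau_fraction` (default
0.3) of each cycle; cycle lengths and R-R intervals are
Normal(mean, CV·mean) truncated positive. A trigger candidate at
R-wave + `r_delay_ms` fires iff the whole 15 ms exposure stays at or below
`exhalation_threshold` (0.05) and at least one detector frame period
(1 s) has elapsed since the previous trigger; the first R-wave is at
t = 0, so the vacuous-gating scan takes exactly 286 s. Gantry stepping is
absorbed into the frame period. Angles are inclusive endpoints,
step 200/285°.

**Known limitation — absolute gated scan time.** At 420/108 bpm with a 30%
window, the plateau (167 ms) is wider than one R-R interval (143 ms), so
almost every respiratory cycle contains a valid beat and the simulated
scans take ~320 s, whereas the real system needed ~10–15 min. The printed
durations imply a per-heartbeat acceptance near 5%, which a 30% window
cannot produce under any exposure-containment convention; the gap is real
hardware overhead (trigger re-arm, gantry settling, signal-conditioning
latency, conservative window detection) that this idealized trigger rule
deliberately does not model. The corresponding scan-time-range check is
left failing rather than tuning the window or inserting ad-hoc dead time.

## CT quantification

`grow_region` is threshold-constrained seeded region growing: connected
components (6- or 26-adjacency; default 6) of the in-window voxel set that
contain a seed. It replaces the interactive region-competition snakes of
the original workflow — at ≥200 HU blood/myocardium contrast the two are
functionally equivalent, and no snake parameters were ever published.
`segment_lv_blood` adds removal of components below
`min_component_voxels` (64) and a 1-voxel closing. On noise-free phantoms
the result equals the ground-truth blood label exactly; at 30 HU noise the
Dice overlap stays above 0.99 and EF is recovered within 0.003.

The myocardial band is the EDT dilation of the blood mask by
`wall_thickness_mm`, excluding the blood itself. The infarct threshold is
`T = μ̂ + k·σ̂` (k = 3) with μ̂, σ̂ estimated from the lower half of the
band's HU distribution and corrected by truncated-normal moments
(σ̂ = s/0.6028, μ̂ = m + λσ̂ for the half-normal): an estimator that is
unbiased on pure noise, reproduces noise-free segmentation exactly
(σ̂ = 0 ⇒ T = the viable level), and is insensitive to infarcts occupying
up to half the wall. A lower fraction of 0.8 was considered and rejected:
with the study-scale ~32% infarct load the upper mode contaminates the
retained sample and pushes T above the infarct HU. Small bright islands
are removed by the same minimum-component rule. All segmentation is
invariant to adding a constant to every HU value (with the blood window
shifted equally) — the infarct threshold is data-driven.

Negative EF (systolic mask larger than diastolic) is returned with a
warning, not clamped: it flags segmentation failure.

## Histology quantification

Background pixels are near-white: darkest channel above 0.84 — equivalent
to a luminance/saturation rule, since min = V(1 − S) in HSV terms. This
margin is ≥2.5 channel-jitter SDs from both the white background and the
pale infarct pink, so misclassification is <0.1% of pixels. The tissue
mask keeps the largest connected component; the enclosed cavity renders
white and is excluded automatically. Within tissue, infarct = saturation
< 0.35 and Rec.601 luma > 0.55 (the rendered viable red sits at S ≈ 0.78,
L ≈ 0.33; infarct pink at S ≈ 0.19, L ≈ 0.79). Per slab, front and back
areas are averaged (trapezoid-like rule — the two faces of a 1 mm slab
give an effective 0.5 mm out-of-plane sampling) and integrated over the
stack; slicing at 0.5 mm instead of 1 mm roughly halves the out-of-plane
bias on the phantom (0.46 vs 0.83 points).

## Statistics

Means/SDs default to the n−1 divisor (both exposed: the source table's
own summary row is internally inconsistent — its AVERAGE/ST.DEV. values
are swapped between the CT and histology columns, which leaves every R²
unaffected). Correlation is squared Pearson; method similarity is a
two-sided paired t-test (the printed pairs give p ≈ 0.478, consistent with
the reported bound p < 0.71); the EF group comparison is a Welch t-test,
chosen because the group variances are visibly unequal (0.11 vs 0.07) and
the original test was unnamed. Outlier exclusion is by explicit subject
ID, mirroring the study's manual removal of its motion-corrupted subject,
never automated.

## Problem sizes and tolerances

Tests and the acceptance script run at the full 77 µm study resolution
(~10⁶-voxel volumes). EF recovery uses 5 phantom pairs per group mean;
the end-to-end cohort uses 8 IR subjects (one motion-corrupted) — matching
the study's group sizes; the gating summary uses 20 seeded schedules.
Noise-free checks are exact (machine precision); noisy recoveries assert
±0.03 EF, ±3 HU on ROI means, and ±3 percentage points on infarct load.

## What passing tests do not show

The phantoms share a geometry family (smooth convex cavity, uniform wall,
wedge infarct) with the assumptions of the segmentation: real hearts have
papillary muscles, trabeculation, partial-volume blur from reconstruction,
beam hardening and anatomy (lungs, ribs) that are all absent here, and the
synthetic CT-vs-histology correlation is consequently near-perfect
(R² → 1 on clean subjects) rather than the ~0.83 seen in vivo. Recovery
within the stated tolerances therefore validates the pipeline's
*consistency and implementation*, not its in-vivo accuracy. X-ray
projection physics, tomographic reconstruction and dose are out of scope
throughout; the motion artifact is injected in image space.
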