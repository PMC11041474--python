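# Methods

`lumbarseq` analyses sagittal cine recordings of the lumbar spine to answer
one question: in what order do the intervertebral segments contribute to the
motion?  The pipeline has five stages — synthetic data, vertebral tracking,
segmental kinematics, peak-sequence classification and inter-rater
reliability — each usable on its own.  This note documents the models,
parameters and numerical choices behind each stage, and what the synthetic
validation does and does not demonstrate.

## The observable

Six vertebrae (L1..S1) define five motion segments (L1L2..L5S1).  For each
segment, the *contribution* at frame-pair *i* is the change of the relative
sagittal angle between its two vertebrae from frame *i* to *i+1*:

    inc_s(i) = [θ_upper(i+1) − θ_lower(i+1)] − [θ_upper(i) − θ_lower(i)]

Contributions are plotted against the *cumulative* rotation of a block of
segments, `x(i) = Σ_{j≤i} Σ_{s∈block} inc_s(j)`, so the x-axis is "how far
the spine has moved", not time.  After low-pass Gaussian smoothing, local
maxima of the contribution curve mark the instant each segment contributes
most; peaks below 0.3° are within measurement error and are discarded.  The
*canonical extension pattern* is a peak in L3L4, then L2L3, then L1L2 within
the last phase of extension.  Only the order of the peaks matters, never
their heights.  L4L5 and L5S1 behave inconsistently (and the lowest segment
suffers pelvic overprojection), so they are excluded from classification by
default and reported descriptively.

## Synthetic kinematics model

No recordings are distributed with the study protocol this package models,
so the simulator is a first-class component, not a test fixture.

A single normalised coordinate *c* ∈ [0, 1] places the whole column along
its flexion(0)–extension(1) path.  The recording traverses *c* in three
phases — neutral → max extension, → max flexion, → max extension — following
a minimum-jerk profile within each phase (zero velocity and acceleration at
the turning points, so no spurious increment spikes at phase boundaries).
Defaults mirror the acquisition protocol: 14 s, 7.5 frames/s, 104 frames,
1024×1024-pixel frames.  14 s × 7.5 fps is 105 samples; the stated frame
count of 104 is kept as the default and is overridable.  The neutral start
sits at c = 0.5, and phase fractions default to 0.2/0.4/0.4 — proportional
to the sweep lengths, so angular speed is comparable across phases.  The
neutral start also makes the flexion trough the unique global minimum of the
cumulative curve, which is what the phase splitter relies on.

Each segment's share of the motion is a Gaussian bump along *c*: segment
angle = total_range · Φ((c−center)/width), with Φ the truncated-Gaussian CDF
normalised over [0, 1].  The ordering of the centres therefore *is* the
ground-truth peak sequence, and per-phase increment sums telescope exactly
to the segment's signed sweep (the conservation property tested to 1e−9).

Default segment parameters (free parameters of the simulator — the study
reports no per-segment amplitudes):

| segment | range (°) | centre | width |
|---------|-----------|--------|-------|
| L1L2    | 6         | 0.94   | 0.05  |
| L2L3    | 8         | 0.88   | 0.05  |
| L3L4    | 10        | 0.82   | 0.05  |
| L4L5    | 16        | 0.40   | 0.12  |
| L5S1    | 13        | 0.25   | 0.12  |

The lower segments carry the most range, consistent with standard lumbar
ROM; their mass arrives early in extension so that the upper-lumbar peaks
fall within the final third of the cumulative range — the geometric
condition the canonical pattern describes.  Measurement noise is additive
zero-mean Gaussian on the *reported* increments (truth is kept separately),
default sd 0.15° per frame-pair, chosen so the 0.3° peak threshold sits at
two standard deviations.

## Phantom rendering

Vertebral bodies are textured quadrilaterals on a planar kinematic chain:
the lowest vertebra is fixed (the pelvis is fixed in the acquisition chair),
each joint sits mid-disc and is carried by the vertebra below.  Texture is a
per-vertebra trabecular speckle fixed in body coordinates (feature scale
≈ 3 px) inside a bright cortical rim, so gradients are informative and
rotate with the body.  The background is a smooth soft-tissue-like mottle,
rendered once per recording (fixed-pattern), so a motionless recording
yields pixel-identical frames.  A detector point-spread blur (σ 0.8 px)
anti-aliases edges.  An optional occlusion band emulates pelvic
overprojection: it washes out contrast and adds per-frame soft-tissue
fluctuation, which is what actually degrades tracking of a static sacrum.
Vertebrae whose corners leave the canvas raise a warning and are flagged;
downstream analysis excludes such recordings.

## Tracking

Each vertebra is delineated by a polygon on the median frame and followed by
maximising a normalized-gradient-field (NGF) similarity over rigid 2-D poses
(rotation about the polygon centroid + translation; no scale — the
source-detector geometry is fixed).  The NGF is ∇I/√(|∇I|²+ε²) with ε
defaulting to 10% of the median gradient magnitude over the template, so
edge orientation drives the match and absolute brightness does not.

The similarity is the energy-normalised squared inner product

    s = Σ_i (r_i·m_i)² / Σ_i |r_i|²|m_i|²  ∈ [0, 1],

where r is the reference NGF rotated with the candidate pose and m the
moving frame's NGF sampled bilinearly at the transformed template pixels.
The energy normalisation matters: bilinear interpolation attenuates the
sampled field at sub-pixel positions, and without it the plain mean squared
inner product is systematically biased toward integer-pixel (and hence
zero-motion) poses.

Search is coarse-to-fine on a 3-level ×2 pyramid, outward from the reference
frame, each frame initialised at its neighbour's pose and bounded (defaults
±6°/frame, ±20 px/frame).  The coarse level localises translation
exhaustively (rotation is unresolvable at that scale); the mid level
consolidates translation at sub-pixel steps; full resolution sweeps the
whole per-frame rotation range densely (0.25° steps), refines on a local
sub-pixel grid, and finishes with Nelder-Mead.  Ties on the coarse grid
break toward the smallest pose change from the previous frame, making the
tracker deterministic.  Images are pre-smoothed (σ 1 px) before gradients:
the smoothed central difference approximates a Gaussian derivative, which is
far more rotation-equivariant than the raw pixel stencil.

On rendered phantoms with known rigid motion the tracker recovers rotation
to ≈ 0.02–0.05° RMS and translation to ≈ 0.01 px.  A caveat: a single
speckle realisation has some net orientation anisotropy, which can leave a
constant rotation offset of up to ≈ 0.04° for a given texture.  It cancels
in per-frame rotation *rates* and averages out over textures, and is an
order of magnitude below the 0.3° threshold, but it is why unbiasedness is
asserted on rates rather than on absolute pose.

A pose is invalid when the transformed polygon exits the image or the match
score falls below a floor (default 0.05).  Manual corrections replace one
frame's pose, re-track the frames beyond it (outward from the reference) and
are recorded in an audit log.

## Phase splitting and classification

Phases are delimited by the extrema of the cumulative curve: the flexion
trough is its unique global minimum; the extension-1 maximum is the global
maximum before it.  Extrema are located on a 3-point median-filtered copy
(single-frame spikes cannot move a boundary) and refined to the raw extremum
within one sample, ties to the earliest frame.  A monotone cumulative curve
(no turning point) is rejected as "not a full cycle".

Within a phase, increments are smoothed with a truncated (4σ), unit-sum
Gaussian kernel with reflected boundaries — DC gain is exactly 1, so a
constant series is unchanged.  Default σ is 2 frame-pairs: small enough to
preserve ≈ 0.3° peaks at 7.5 fps, large enough to suppress single-frame
noise.  Smoothing runs on the full recording before phase restriction, so
window edges are not reflection artefacts.  Flexion is analysed with the
sign flipped so that contribution peaks are maxima in either direction.

Peaks are strict local maxima (plateaus resolve to their midpoint; endpoints
are never peaks) at or above the 0.3° threshold.  The classifier checks
that, within the final third of the phase's cumulative range ("last phase",
configurable), every canonical segment has a retained peak and the *last*
peak per segment is strictly ordered L3L4 < L2L3 < L1L2; position ties break
toward non-match.  A recording with any invalid tracking is excluded, not
classified.

Cohort consistency follows the 80% rule: the pattern is consistent at a time
point when at least 80% of analyzable recordings show it.

## Reliability

Two analysts re-measure the same frame-pair rotation series; each
(segment, recording) pair yields one n×2 ratings table.  The default
statistic is ICC(3,1) — two-way mixed, single measure, consistency:

    ICC(3,1) = (MS_rows − MS_error) / (MS_rows + (k−1)·MS_error).

"Two-way mixed" does not pin down single/average measures or
consistency/absolute agreement; consistency is the default here because the
comparison is between re-measurements of the same sequences, not about rater
interchangeability — the absolute-agreement single-measure form is available
behind a flag.  Values above 0.60 are adequate.  Per-segment means across
recordings are rounded to 3 decimals for display.  Degenerate tables
(n < 3, missing cells) are rejected; zero between-target variance follows
the formula (and may be ≤ 0 or NaN).

## Problem sizes used in validation

The test-suite and acceptance phantoms are scaled-down versions of the
protocol geometry, a deliberate package choice: a 300×300 canvas with a
90×60 px body for rotation-recovery runs (51 frames at 0.5°/frame), a
108×170 canvas for the field-of-view-loss scenario (24 frames), and
kinematics-only simulations (no rendering) for the 100-seed classification
experiments.  Classification accuracy at the default noise is checked
against a 3-point noise grid (sd 0.05/0.15/0.45°) for monotonicity.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the pipeline recovers what the generator put
in: exact kinematics arithmetic, sub-0.1° rigid tracking on well-textured
phantoms, correct peak ordering under the stated noise, and exact
reproduction of the published summary numbers from their inputs.  The
phantom does not emulate out-of-plane motion, perspective/parallax,
scatter, exposure drift, or genuinely deformable anatomy; real fluoroscopy
is harder than this phantom in all of those ways, so synthetic accuracy
numbers are upper bounds on real-data performance.  Inter-subject
variability of the true peak sequence is a modelling input here (the
generator's centres), not a finding.

## Known limitations

* Whole-body rigid pose stands in for endplate-based angle definitions.
* Translation (shear) kinematics and centre-of-rotation estimation are out
  of scope.
* The speckle-anisotropy rotation offset described above (≤ ≈ 0.04°).
* The classifier's "last phase" window (final 1/3 of cumulative range) is a
  convention; it is configurable and always reported in output.
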