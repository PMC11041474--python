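# lumbarseq

Analysis of the **sequence of segmental contribution** in the lumbar spine
from sagittal cine (fluoroscopic) recordings.

During a maximum extension–flexion–extension cycle, each intervertebral
segment (L1L2 … L5S1) contributes its rotation at a characteristic moment of
the movement.  Plotting every segment's inter-frame rotation against the
cumulative rotation of the whole block turns that timing into a sequence of
peaks; in healthy extension the upper lumbar spine typically peaks in the
order **L3L4 → L2L3 → L1L2** during the last phase of the motion.
`lumbarseq` implements the full measurement chain needed to make and test
that observation:

1. **`synth`** — a ground-truth simulator: parametric segmental kinematics
   (Gaussian contribution bumps along a normalised motion coordinate,
   minimum-jerk phase profiles, configurable noise) plus a phantom renderer
   that draws textured vertebral bodies on a kinematic chain, with optional
   pelvic-overprojection occlusion.
2. **`tracking`** — rigid 2-D tracking of user-drawn vertebral template
   polygons through all frames by best-fit matching of **normalized gradient
   field** images, coarse-to-fine, with manual-correction support.
3. **`kinematics`** — exact per-segment inter-frame rotation increments,
   cumulative block rotation, and phase splitting at the extrema of the
   cumulative curve.
4. **`pattern`** — low-pass Gaussian smoothing, detection of contribution
   peaks above the 0.3° measurement-error threshold, classification of the
   peak sequence against the canonical pattern, and cohort consistency
   summaries (80% rule).
5. **`reliability`** — inter-rater agreement via the two-way mixed
   intraclass correlation coefficient, ICC(3,1) =
   (MS_rows − MS_error)/(MS_rows + (k−1)·MS_error), with the 0.60 adequacy
   rule and per-segment summary tables.

The mathematical and numerical details are in [`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a recording with the canonical ground-truth ordering, classify it,
and summarise a small cohort:

```python
import lumbarseq as lq

rec, analysis = lq.analyze_simulated(seed=1)
print(rec.n_frames, rec.peak_sequence_true[-3:])
print(analysis.extension.matches_canonical)
for p in analysis.extension.ordered_peaks:
    print(f"{p.segment_label}: peak at {p.position:.1f} deg, height {p.height:.2f} deg")
```

prints

```
104 ('L3L4', 'L2L3', 'L1L2')
True
L5S1: peak at 10.0 deg, height 1.42 deg
L4L5: peak at 23.2 deg, height 1.92 deg
L3L4: peak at 38.6 deg, height 1.61 deg
L2L3: peak at 45.4 deg, height 1.11 deg
L1L2: peak at 48.1 deg, height 0.77 deg
```

The recording has 104 frames (14 s at 7.5 frames/s).  Each line is a
segment's retained contribution peak: its position on the cumulative
rotation axis (degrees of block rotation completed when that segment
contributed most) and the smoothed peak height in degrees per frame-pair.
The lower segments (L5S1, L4L5) peak early in extension; the upper three
peak in the last third of the ~53° cumulative range in the canonical order
L3L4 → L2L3 → L1L2, so `matches_canonical` is `True`.

Reliability of two raters' measurements of the same series:

```python
import numpy as np
rng = np.random.default_rng(0)
truth = rng.normal(0, 1.0, 30)
icc = lq.icc_from_rater_series(truth + rng.normal(0, 0.3, 30),
                               truth + rng.normal(0, 0.3, 30))
print(f"ICC(3,1) = {icc:.3f}")   # ICC(3,1) = 0.885
```

## Command line

```bash
lumbarseq simulate --seed 1 --out bundle/          # frames.tif, templates.json, ground_truth.csv
lumbarseq track --frames bundle/frames.tif --templates bundle/templates.json --out poses.csv
lumbarseq kinematics --poses poses.csv --out kin/
lumbarseq pattern --poses poses.csv --out classification.json
lumbarseq icc --rater-a a.csv --rater-b b.csv --out icc.csv
lumbarseq full --seed 1 --participants 11 --out cohort.json
```

Exit codes: 0 success, 2 validation error, 3 I/O error, 4 analysis produced
exclusions only.  All stage parameters live in a YAML `PipelineConfig`
(`--config`), which round-trips losslessly.

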