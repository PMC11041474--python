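"""Contribution curves, peak detection and sequence classification.

The headline observable is the *sequence of segmental contribution*: the
order in which the intervertebral segments reach their maximum inter-frame
rotation (peak contribution) during a motion phase.  The canonical
extension pattern is a peak in L3L4, then L2L3, then L1L2 in the last
phase of extension; L4L5 and L5S1 are excluded from classification by
default (their patterns are inconsistent and the lowest segment suffers
pelvic overprojection) but remain available descriptively.

Each segment's raw increment series is smoothed with a low-pass Gaussian
digital filter, plotted against the cumulative block rotation, and peaks
below the measurement-error threshold (0.3 degrees) are discarded.  Only
the order of the peaks matters, not their heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .kinematics import CumulativeAxis, PhaseWindow, SegmentSeries
from .synth import ValidationError

PEAK_THRESHOLD_DEG = 0.3  # peaks below this fall within measurement error
CANONICAL_PATTERN = ("L3L4", "L2L3", "L1L2")
DEFAULT_LAST_PHASE_FRACTION = 1.0 / 3.0
DEFAULT_SIGMA = 2.0  # frame-pairs


@dataclass
class ContributionCurve:
    """Smoothed increment-vs-cumulative-rotation curve of one segment in one phase."""

    segment_label: str
    x: np.ndarray  # cumulative block rotation (deg) per frame-pair
    y: np.ndarray  # smoothed segment increment (deg) per frame-pair
    smoothing_sigma: float
    valid: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValidationError("x and y must share length")


@dataclass(frozen=True)
class PeakEvent:
    """A retained local maximum of a contribution curve."""

    segment_label: str
    position: float  # cumulative rotation (deg) at the peak
    height: float  # smoothed increment (deg)
    index: int  # frame-pair index within the phase


@dataclass
class SequenceClassification:
    """Outcome of classifying one phase of one recording."""

    phase: str
    ordered_peaks: list[PeakEvent]
    last_phase_window: float  # fraction of the cumulative range inspected
    matches_canonical: bool
    canonical_pattern: tuple[str, ...] = CANONICAL_PATTERN
    excluded: bool = False
    exclusion_reason: str = ""
    peaks_by_segment: dict[str, list[PeakEvent]] = field(default_factory=dict)


def gaussian_smooth(values: np.ndarray, sigma: float) -> np.ndarray:
    """Low-pass Gaussian digital filter.

    Discrete Gaussian convolution with reflected boundary handling and a
    unit-sum kernel (DC gain exactly 1), truncated at 4 sigma.
    """
    values = np.asarray(values, dtype=float)
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    if values.ndim != 1 or len(values) < 3:
        raise ValidationError("need a 1-D series of length >= 3")
    radius = max(int(np.ceil(4.0 * sigma)), 1)
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(values, radius, mode="symmetric")
    return np.convolve(padded, kernel, mode="valid")


def smooth_curve(
    series: SegmentSeries,
    cumulative: CumulativeAxis | np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    phase: PhaseWindow | None = None,
    flip_sign: bool = False,
) -> ContributionCurve:
    """Smooth a segment's increments and pair them with the cumulative axis.

    When ``phase`` is given, both series are restricted to that frame-pair
    window *after* smoothing (so the filter sees the full recording and the
    window edges are not reflection artefacts).  ``flip_sign`` negates the
    increments and reverses the cumulative direction -- used for the flexion
    phase so that contribution peaks are maxima in either direction.
    """
    x = cumulative.values_deg if isinstance(cumulative, CumulativeAxis) else np.asarray(cumulative, float)
    if len(x) != series.n_pairs:
        raise ValidationError("cumulative axis and series must share length")
    y = gaussian_smooth(series.increments_deg, sigma)
    valid = series.all_valid
    if phase is not None:
        sl = phase.slice()
        x, y = x[sl], y[sl]
        valid = bool(series.valid_mask[sl].all())
    if flip_sign:
        y = -y
        x = -x
    # anchor the phase's cumulative progress at zero
    if len(x):
        x = x - x[0]
    return ContributionCurve(series.segment_label, x, y, sigma, valid=valid)


def detect_peaks(
    curve: ContributionCurve, threshold: float = PEAK_THRESHOLD_DEG
) -> list[PeakEvent]:
    """Strict local maxima of the smoothed curve at or above ``threshold``.

    Plateaus are resolved to their midpoint.  Peaks are reported in order
    of increasing position.  Endpoints are never peaks.
    """
    y = curve.y
    if len(y) < 3:
        return []
    idx, props = find_peaks(y, plateau_size=1)
    events = []
    for i, le, re in zip(idx, props["left_edges"], props["right_edges"]):
        mid = (le + re) // 2
        height = y[mid]
        if height >= threshold:
            events.append(
                PeakEvent(curve.segment_label, float(curve.x[mid]), float(height), int(mid))
            )
    events.sort(key=lambda e: (e.position, e.index))
    return events


def classify_sequence(
    curves: dict[str, ContributionCurve] | list[ContributionCurve],
    phase: str,
    canonical_pattern: tuple[str, ...] = CANONICAL_PATTERN,
    last_phase_fraction: float = DEFAULT_LAST_PHASE_FRACTION,
    threshold: float = PEAK_THRESHOLD_DEG,
) -> SequenceClassification:
    """Classify the segmental-contribution sequence of one phase.

    ``matches_canonical`` is true iff, within the final ``last_phase_fraction``
    of the phase's cumulative rotation range, every canonical segment has at
    least one retained peak and the *last* retained peak of each canonical
    segment occurs strictly before that of the next (ties break toward
    non-match).  A curve flagged invalid (field-of-view loss) excludes the
    recording from classification.
    """
    if not isinstance(curves, dict):
        curves = {c.segment_label: c for c in curves}
    if not 0.0 < last_phase_fraction <= 1.0:
        raise ValidationError("last_phase_fraction must be in (0, 1]")
    missing = [s for s in canonical_pattern if s not in curves]
    if missing:
        raise ValidationError(f"curves missing for canonical segments: {missing}")

    invalid = [label for label, c in curves.items() if not c.valid]
    if invalid:
        return SequenceClassification(
            phase=phase,
            ordered_peaks=[],
            last_phase_window=last_phase_fraction,
            matches_canonical=False,
            canonical_pattern=canonical_pattern,
            excluded=True,
            exclusion_reason=f"invalid tracking for segments: {sorted(invalid)}",
        )

    peaks_by_segment = {label: detect_peaks(c, threshold) for label, c in curves.items()}
    all_peaks = sorted(
        (p for peaks in peaks_by_segment.values() for p in peaks),
        key=lambda e: (e.position, e.index),
    )

    some = next(iter(curves.values()))
    x0, x1 = float(some.x[0]), float(some.x[-1])
    window_start = x1 - last_phase_fraction * (x1 - x0)

    last_positions = []
    ok = True
    for label in canonical_pattern:
        in_window = [p for p in peaks_by_segment[label] if p.position >= window_start]
        if not in_window:
            ok = False
            break
        last_positions.append(in_window[-1].position)
    if ok:
        ok = all(a < b for a, b in zip(last_positions, last_positions[1:]))

    return SequenceClassification(
        phase=phase,
        ordered_peaks=all_peaks,
        last_phase_window=last_phase_fraction,
        matches_canonical=bool(ok),
        canonical_pattern=canonical_pattern,
        peaks_by_segment=peaks_by_segment,
    )


def consistency_summary(classifications: pd.DataFrame) -> dict:
    """Cohort-level consistency of the motion pattern.

    ``classifications`` needs columns participant, time_point,
    matches_canonical, excluded.  Excluded recordings are dropped from the
    denominators but counted.  A consistent cohort pattern requires the
    canonical fraction to reach 80% at every time point.
    """
    required = {"participant", "time_point", "matches_canonical", "excluded"}
    if classifications is None or len(classifications) == 0:
        raise ValidationError("no classifications supplied")
    missing = required - set(classifications.columns)
    if missing:
        raise ValidationError(f"classification table missing columns: {sorted(missing)}")

    df = classifications.copy()
    analyzable = df[~df["excluded"].astype(bool)]
    if len(analyzable) == 0:
        raise ValidationError("all recordings excluded")

    per_tp = {}
    for tp, grp in analyzable.groupby("time_point"):
        per_tp[tp] = {
            "n": int(len(grp)),
            "n_canonical": int(grp["matches_canonical"].sum()),
            "fraction_percent": 100.0 * grp["matches_canonical"].mean(),
        }
    overall = 100.0 * analyzable["matches_canonical"].mean()

    tps = sorted(per_tp)
    by_participant = analyzable.groupby("participant")["matches_canonical"]
    seen_tps = analyzable.groupby("participant")["time_point"].nunique()
    consistent_participants = sorted(
        p
        for p, all_canon in by_participant.all().items()
        if all_canon and seen_tps[p] == len(tps)
    )

    return {
        "per_time_point": per_tp,
        "overall_percent": overall,
        "n_analyzable": int(len(analyzable)),
        "n_canonical": int(analyzable["matches_canonical"].sum()),
        "n_excluded": int(df["excluded"].astype(bool).sum()),
        "consistent_participants": consistent_participants,
        "cohort_consistent": all(
            v["fraction_percent"] >= 80.0 for v in per_tp.values()
        ),
    }


def plot_contributions(curves, peaks_by_segment=None, ax=None, threshold=PEAK_THRESHOLD_DEG):
    """Plot smoothed segmental contributions against cumulative block rotation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    if isinstance(curves, dict):
        curves = list(curves.values())
    for c in curves:
        (line,) = ax.plot(c.x, c.y, label=c.segment_label)
        if peaks_by_segment and c.segment_label in peaks_by_segment:
            pk = peaks_by_segment[c.segment_label]
            ax.plot([p.position for p in pk], [p.height for p in pk], "v",
                    color=line.get_color())
    ax.axhline(threshold, ls=":", color="grey", lw=1)
    ax.set_xlabel("cumulative block rotation (deg)")
    ax.set_ylabel("segment rotation between frames (deg)")
    ax.legend(fontsize=8)
    return ax
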