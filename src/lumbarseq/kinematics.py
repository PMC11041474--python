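"""Segmental kinematics: inter-frame rotation increments and cumulative block rotation.

Pure arithmetic on vertebral poses.  A *segment* is a pair of adjacent
vertebrae (e.g. L3L4); its increment at frame-pair ``i`` is the change in
relative angle (upper minus lower vertebra) between frames ``i`` and
``i+1``.  The *cumulative axis* is the running sum of a block of segments'
increments -- the x-axis against which segmental contributions are plotted.
Extension is taken as the positive rotation direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .synth import ValidationError

PHASE_ORDER = ("extension1", "flexion", "extension2")


@dataclass
class SegmentSeries:
    """Per frame-pair signed rotation increments of one segment, degrees."""

    segment_label: str
    increments_deg: np.ndarray
    valid_mask: np.ndarray  # per frame-pair; False where either pose invalid

    def __post_init__(self) -> None:
        self.increments_deg = np.asarray(self.increments_deg, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.increments_deg.shape != self.valid_mask.shape:
            raise ValidationError("increments and valid_mask must share shape")

    @property
    def n_pairs(self) -> int:
        return len(self.increments_deg)

    @property
    def all_valid(self) -> bool:
        return bool(self.valid_mask.all())


@dataclass
class CumulativeAxis:
    """Cumulative signed rotation of a block of segments, per frame-pair."""

    block_labels: tuple[str, ...]
    values_deg: np.ndarray

    def __post_init__(self) -> None:
        self.values_deg = np.asarray(self.values_deg, dtype=float)


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open frame-pair index range [start, stop) of one motion phase."""

    label: str
    start: int
    stop: int

    def slice(self) -> slice:
        return slice(self.start, self.stop)


def _angles_and_valid(poses) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of VertebraPose, a DataFrame, or a plain angle array."""
    if isinstance(poses, pd.DataFrame):
        df = poses.sort_values("frame_index" if "frame_index" in poses else "frame")
        angles = df["rotation_deg"].to_numpy(dtype=float)
        valid = (
            df["valid"].to_numpy(dtype=bool)
            if "valid" in df
            else np.ones(len(df), dtype=bool)
        )
        return angles, valid
    if hasattr(poses, "__len__") and len(poses) and hasattr(poses[0], "rotation_deg"):
        angles = np.array([p.rotation_deg for p in poses], dtype=float)
        valid = np.array([p.valid for p in poses], dtype=bool)
        return angles, valid
    arr = np.asarray(poses, dtype=float)
    return arr, np.ones(arr.shape, dtype=bool)


def compute_segment_series(upper_poses, lower_poses, segment_label: str = "") -> SegmentSeries:
    """Inter-frame rotation increments of the upper relative to the lower vertebra.

    ``increment(i) = [th_u(i+1) - th_l(i+1)] - [th_u(i) - th_l(i)]`` exactly;
    no smoothing is applied at this stage.  A frame-pair is valid only if
    both poses of both frames are valid.
    """
    a_u, v_u = _angles_and_valid(upper_poses)
    a_l, v_l = _angles_and_valid(lower_poses)
    if a_u.shape != a_l.shape:
        raise ValidationError("upper and lower vertebra must have equal frame counts")
    if len(a_u) < 2:
        raise ValidationError("need at least two frames")
    rel = a_u - a_l
    increments = np.diff(rel)
    valid = (v_u & v_l)[1:] & (v_u & v_l)[:-1]
    return SegmentSeries(segment_label, increments, valid)


def compute_cumulative(
    series: dict[str, SegmentSeries] | list[SegmentSeries],
    block_labels: tuple[str, ...],
) -> CumulativeAxis:
    """Running sum of the block's increments: ``values(i) = sum_{j<=i} sum_s inc_s(j)``."""
    if not isinstance(series, dict):
        series = {s.segment_label: s for s in series}
    missing = [b for b in block_labels if b not in series]
    if missing:
        raise ValidationError(f"block labels absent from series: {missing}")
    lengths = {series[b].n_pairs for b in block_labels}
    if len(lengths) != 1:
        raise ValidationError("all series in a block must share frame count")
    total = np.sum([series[b].increments_deg for b in block_labels], axis=0)
    return CumulativeAxis(tuple(block_labels), np.cumsum(total))


def split_phases(cumulative: CumulativeAxis) -> list[PhaseWindow]:
    """Locate the three motion phases from the cumulative curve's extrema.

    The cycle is extension -> flexion -> extension, so the cumulative block
    rotation rises to a global maximum, falls to a global minimum, then
    rises again.  Extrema are located on a 3-point median-filtered copy of
    the curve (to resist single-frame noise) and refined to the raw curve's
    extremum within one sample; ties resolve to the earliest frame.
    Raises if the curve is monotone (the recording is not a full cycle).
    """
    c = np.asarray(cumulative.values_deg, dtype=float)
    n = len(c)
    if n < 5:
        raise ValidationError("cumulative curve too short to split into phases")
    smooth = medfilt(c, kernel_size=3)

    def refine(curve: np.ndarray, i: int, lo_bound: int, find_max: bool) -> int:
        # the median filter flattens a sharp apex; take the raw extremum
        # within one sample of the filtered one (earliest on ties)
        lo = max(i - 1, lo_bound)
        hi = min(i + 2, len(curve))
        window = curve[lo:hi]
        j = int(np.argmax(window)) if find_max else int(np.argmin(window))
        return lo + j

    # the flexion trough is the unique global minimum (both extension phases
    # end high); locate it first, then the maximum before it
    i_min_s = int(np.argmin(smooth))
    if i_min_s < 2 or i_min_s >= n - 1:
        raise ValidationError("cumulative curve is monotone; not a full motion cycle")
    i_max = refine(c, int(np.argmax(smooth[:i_min_s])), 0, find_max=True)
    if i_max < 1 or i_max >= i_min_s:
        raise ValidationError("cumulative curve is monotone; not a full motion cycle")
    i_min = refine(c, i_min_s, i_max + 1, find_max=False)
    if i_min >= n - 1:
        raise ValidationError("cumulative curve is monotone; not a full motion cycle")

    return [
        PhaseWindow("extension1", 0, i_max + 1),
        PhaseWindow("flexion", i_max + 1, i_min + 1),
        PhaseWindow("extension2", i_min + 1, n),
    ]


def series_frame(series: dict[str, SegmentSeries]) -> pd.DataFrame:
    """Tidy (frame_pair, segment, increment_deg, valid) table."""
    rows = []
    for label, s in series.items():
        for i, (inc, v) in enumerate(zip(s.increments_deg, s.valid_mask)):
            rows.append(
                {"frame_pair": i, "segment": label, "increment_deg": inc, "valid": v}
            )
    return pd.DataFrame(rows)


def cumulative_frame(axis: CumulativeAxis) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame_pair": np.arange(len(axis.values_deg)),
            "block": "".join((axis.block_labels[0][:2], "-", axis.block_labels[-1][-2:])),
            "cumulative_deg": axis.values_deg,
        }
    )
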