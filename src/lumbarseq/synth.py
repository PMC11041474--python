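"""Synthetic lumbar kinematics and phantom cine frames.

Generates ground-truth flexion--extension recordings of the lumbar column
(L1..S1, five intervertebral segments) so that every downstream stage --
vertebral tracking, segmental kinematics, peak-sequence classification,
reliability -- can be exercised against a known truth without any imaging
data.

The motion model is deliberately minimal.  A single normalised cumulative
coordinate ``c`` in [0, 1] describes the position of the whole block along
its motion path (0 = maximum flexion, 1 = maximum extension).  The recording
traverses ``c`` up, down and up again (extension -> flexion -> extension),
each phase following a minimum-jerk time profile so increments vanish
smoothly at the turning points.  Each segment contributes a unimodal,
Gaussian-shaped share of rotation along ``c``: segment angle is the
integral of a Gaussian bump centred at ``contribution_center`` with width
``contribution_width``, scaled so the segment sweeps ``total_range_deg``
over a full traversal.  The ordering of the centres therefore *is* the
ground-truth peak sequence.

Reported increments optionally carry additive zero-mean Gaussian
measurement noise; the true increments are kept alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

VERTEBRAE = ("L1", "L2", "L3", "L4", "L5", "S1")
SEGMENTS = ("L1L2", "L2L3", "L3L4", "L4L5", "L5S1")

PHASE_LABELS = ("extension1", "flexion", "extension2")


class ValidationError(ValueError):
    """A protocol, spec or geometry field is out of its allowed range."""


@dataclass(frozen=True)
class MotionProtocol:
    """Acquisition protocol of one cine recording.

    Defaults follow the sagittal fluoroscopy protocol: from a neutral
    seated position, maximum extension, then maximum flexion, then a
    return to maximum extension, in 14 seconds at 7.5 frames per second,
    104 frames in total.  ``neutral_start`` is the normalised position of
    the neutral posture along the flexion(0)--extension(1) path; phase
    fractions default to the relative sweep lengths (0.5 : 1 : 1) so
    angular speed is comparable across phases.
    """

    duration_s: float = 14.0
    frame_rate_hz: float = 7.5
    n_frames: int = 104
    neutral_start: float = 0.5
    phase_plan: tuple[tuple[str, float], ...] = (
        ("extension1", 0.2),
        ("flexion", 0.4),
        ("extension2", 0.4),
    )

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValidationError("duration_s and frame_rate_hz must be positive")
        fractions = [f for _, f in self.phase_plan]
        if any(f <= 0 for f in fractions):
            raise ValidationError("phase_plan: every phase fraction must be positive")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValidationError("phase_plan: phase fractions must sum to 1.0")
        labels = [lab for lab, _ in self.phase_plan]
        if labels != list(PHASE_LABELS):
            raise ValidationError(
                f"phase_plan: phase labels must be {PHASE_LABELS} in order, got {labels}"
            )
        if not 0.0 <= self.neutral_start < 1.0:
            raise ValidationError("neutral_start must lie in [0, 1)")


@dataclass(frozen=True)
class SegmentSpec:
    """One segment's share of the motion."""

    total_range_deg: float
    contribution_center: float
    contribution_width: float
    noise_sd_deg: float = 0.15

    def __post_init__(self) -> None:
        if self.total_range_deg <= 0:
            raise ValidationError("total_range_deg must be > 0")
        if self.contribution_width <= 0:
            raise ValidationError("contribution_width must be > 0")
        if not 0.0 <= self.contribution_center <= 1.0:
            raise ValidationError("contribution_center must lie in [0, 1]")
        if self.noise_sd_deg < 0:
            raise ValidationError("noise_sd_deg must be >= 0")


def default_segment_specs(noise_sd_deg: float = 0.15) -> dict[str, SegmentSpec]:
    """Default per-segment kinematics.

    Ranges approximate standard sagittal lumbar segmental ROM; contribution
    centres place the upper-lumbar peaks in the last third of extension in
    the canonical order L3L4 -> L2L3 -> L1L2, with the two lowest segments
    contributing earlier in the motion.
    """
    return {
        "L1L2": SegmentSpec(6.0, 0.94, 0.05, noise_sd_deg),
        "L2L3": SegmentSpec(8.0, 0.88, 0.05, noise_sd_deg),
        "L3L4": SegmentSpec(10.0, 0.82, 0.05, noise_sd_deg),
        "L4L5": SegmentSpec(16.0, 0.40, 0.12, noise_sd_deg),
        "L5S1": SegmentSpec(13.0, 0.25, 0.12, noise_sd_deg),
    }


@dataclass(frozen=True)
class SegmentKinematicsSpec:
    """Per-segment motion specification for the whole column."""

    segments: dict[str, SegmentSpec] = field(default_factory=default_segment_specs)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("at least one segment required")

    @property
    def segment_labels(self) -> tuple[str, ...]:
        return tuple(self.segments)

    @property
    def peak_sequence_true(self) -> tuple[str, ...]:
        """Segment labels ordered by contribution centre (early to late)."""
        return tuple(
            sorted(self.segments, key=lambda s: self.segments[s].contribution_center)
        )


@dataclass
class GroundTruthRecording:
    """Noise-free vertebral angles plus true and reported segment increments.

    ``angles`` has shape (n_frames, n_vertebrae); vertebra order is top to
    bottom (L1 first, S1 last, S1 held fixed at 0 deg).  Increment arrays
    have shape (n_frames - 1, n_segments).  Extension is the positive
    rotation direction.
    """

    protocol: MotionProtocol
    spec: SegmentKinematicsSpec
    vertebra_labels: tuple[str, ...]
    segment_labels: tuple[str, ...]
    angles: np.ndarray
    segment_increments_true: np.ndarray
    segment_increments_reported: np.ndarray
    cumulative_coordinate: np.ndarray  # normalised c(t), shape (n_frames,)
    peak_sequence_true: tuple[str, ...]
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def angles_frame(self) -> pd.DataFrame:
        """Tidy per-frame absolute angles."""
        n, m = self.angles.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n), m),
                "vertebra": np.tile(self.vertebra_labels, n),
                "angle_deg": self.angles.ravel(),
            }
        )


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Smooth 0->1 profile with zero velocity and acceleration at both ends."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def phase_boundary_frames(protocol: MotionProtocol) -> list[int]:
    """Frame indices at which phases start/end (len = n_phases + 1).

    Boundaries are rounded to the nearest frame so each phase traverses its
    full normalised range exactly.
    """
    n = protocol.n_frames
    cum = np.cumsum([f for _, f in protocol.phase_plan])
    bounds = [0] + [int(round(c * (n - 1))) for c in cum]
    bounds[-1] = n - 1
    if any(b1 - b0 < 1 for b0, b1 in zip(bounds, bounds[1:])):
        raise ValidationError("phase plan allocates fewer than 1 frame to a phase")
    return bounds


def cumulative_profile(protocol: MotionProtocol) -> np.ndarray:
    """Normalised cumulative coordinate c(t) in [0, 1] for every frame.

    Traverses 0 -> 1 (extension1), 1 -> 0 (flexion), 0 -> 1 (extension2)
    following a minimum-jerk profile within each phase; phase boundaries
    fall exactly on frame samples.
    """
    n = protocol.n_frames
    c = np.empty(n)
    endpoints = {
        "extension1": (protocol.neutral_start, 1.0),
        "flexion": (1.0, 0.0),
        "extension2": (0.0, 1.0),
    }
    bounds = phase_boundary_frames(protocol)
    for (label, _), b0, b1 in zip(protocol.phase_plan, bounds, bounds[1:]):
        tau = np.linspace(0.0, 1.0, b1 - b0 + 1)
        a, b = endpoints[label]
        c[b0 : b1 + 1] = a + (b - a) * _minimum_jerk(tau)
    return c


def _segment_angle(spec: SegmentSpec, c: np.ndarray) -> np.ndarray:
    """Segment rotation angle (deg) as a function of the cumulative coordinate.

    Integral of a Gaussian bump centred at ``contribution_center`` with sd
    ``contribution_width``, normalised so a 0->1 traversal sweeps exactly
    ``total_range_deg``.
    """
    mu, w = spec.contribution_center, spec.contribution_width
    z = (np.asarray(c, dtype=float) - mu) / (w * np.sqrt(2.0))
    z0 = (0.0 - mu) / (w * np.sqrt(2.0))
    z1 = (1.0 - mu) / (w * np.sqrt(2.0))
    phi = (erf(z) - erf(z0)) / (erf(z1) - erf(z0))
    return spec.total_range_deg * phi


def generate_kinematics(
    spec: SegmentKinematicsSpec | None = None,
    protocol: MotionProtocol | None = None,
    seed: int = 0,
) -> GroundTruthRecording:
    """Generate one ground-truth recording.

    Deterministic for a fixed seed.  S1 is held fixed; each vertebra's
    absolute angle is the sum of the segment angles below it.  Reported
    increments are the true increments plus i.i.d. zero-mean Gaussian
    noise of per-segment sd ``noise_sd_deg``.
    """
    spec = spec if spec is not None else SegmentKinematicsSpec()
    protocol = protocol if protocol is not None else MotionProtocol()
    rng = np.random.default_rng(seed)

    c = cumulative_profile(protocol)
    seg_labels = spec.segment_labels
    seg_angles = np.column_stack(
        [_segment_angle(spec.segments[s], c) for s in seg_labels]
    )  # (n_frames, n_segments): rotation of upper relative to lower vertebra

    # Stack vertebra absolute angles bottom-up: S1 fixed at 0.
    n_seg = len(seg_labels)
    n_vert = n_seg + 1
    angles = np.zeros((protocol.n_frames, n_vert))
    # vertebra order top to bottom; vertebra j sits above segment j
    for j in range(n_vert - 2, -1, -1):
        angles[:, j] = angles[:, j + 1] + seg_angles[:, j]

    increments_true = np.diff(seg_angles, axis=0)
    noise = np.column_stack(
        [
            rng.normal(0.0, spec.segments[s].noise_sd_deg, protocol.n_frames - 1)
            if spec.segments[s].noise_sd_deg > 0
            else np.zeros(protocol.n_frames - 1)
            for s in seg_labels
        ]
    )
    increments_reported = increments_true + noise

    vert_labels = (
        VERTEBRAE
        if seg_labels == SEGMENTS
        else tuple(lab[: len(lab) // 2] for lab in seg_labels)
        + (seg_labels[-1][len(seg_labels[-1]) // 2 :],)
    )

    return GroundTruthRecording(
        protocol=protocol,
        spec=spec,
        vertebra_labels=vert_labels,
        segment_labels=seg_labels,
        angles=angles,
        segment_increments_true=increments_true,
        segment_increments_reported=increments_reported,
        cumulative_coordinate=c,
        peak_sequence_true=spec.peak_sequence_true,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Phantom rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of the rendered phantom column.

    The default canvas matches the acquisition frame size (1024 x 1024
    pixels); vertebral bodies are drawn as high-contrast textured
    quadrilaterals connected by a planar kinematic chain with the lowest
    vertebra fixed.
    """

    image_shape: tuple[int, int] = (1024, 1024)  # (rows, cols)
    body_width_px: float = 110.0
    body_height_px: float = 70.0
    disc_gap_px: float = 26.0
    column_x_px: float | None = None  # default: image centre
    background_level: float = 0.25
    body_level: float = 0.55
    texture_amplitude: float = 0.18
    rim_width_px: float = 5.0
    rim_level: float = 0.92
    noise_sd: float = 0.02  # additive pixel noise on [0, 1] scale
    background_smooth_px: float = 3.0  # soft-tissue-like blur of the background
    psf_sigma_px: float = 0.8  # detector point-spread blur (also anti-aliases edges)
    occlusion_band: tuple[int, int] | None = None  # (row_start, row_stop)
    occlusion_alpha: float = 0.85
    occlusion_level: float = 0.6
    occlusion_noise_sd: float = 0.015  # per-frame soft-tissue fluctuation in the band
    template_margin: float = 1.0  # polygon drawn at the body outline

    def __post_init__(self) -> None:
        if self.body_width_px <= 0 or self.body_height_px <= 0:
            raise ValidationError("body dimensions must be positive")
        if min(self.image_shape) < 8:
            raise ValidationError("image too small")


def _rot(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def vertebra_world_poses(
    recording: GroundTruthRecording, geometry: GeometryConfig
) -> tuple[np.ndarray, np.ndarray]:
    """World pose of every vertebral body centre at every frame.

    Returns ``(centers, angles)`` with centers shape (n_frames, n_vert, 2)
    in (x, y) pixel coordinates (origin top-left, y down) and angles in
    degrees (positive counter-clockwise in image coordinates).  The column
    is a planar chain: the lowest vertebra is fixed, each joint sits mid-disc
    and is carried by the vertebra below it.
    """
    n_frames, n_vert = recording.angles.shape
    h, w = geometry.image_shape
    cx = geometry.column_x_px if geometry.column_x_px is not None else w / 2.0
    pitch = geometry.body_height_px + geometry.disc_gap_px
    col_height = (n_vert - 1) * pitch
    y_top = (h - col_height) / 2.0
    # neutral centres, top (index 0) to bottom
    neutral = np.array([[cx, y_top + j * pitch] for j in range(n_vert)])
    joints_neutral = (neutral[:-1] + neutral[1:]) / 2.0

    centers = np.empty((n_frames, n_vert, 2))
    angles = recording.angles  # degrees, anatomical extension positive
    for t in range(n_frames):
        centers[t, -1] = neutral[-1]
        for j in range(n_vert - 2, -1, -1):
            lower_c = centers[t, j + 1]
            j_world = lower_c + _rot(angles[t, j + 1]) @ (
                joints_neutral[j] - neutral[j + 1]
            )
            centers[t, j] = j_world + _rot(angles[t, j]) @ (
                neutral[j] - joints_neutral[j]
            )
    return centers, angles.copy()


def _body_corners(geometry: GeometryConfig, margin: float = 1.0) -> np.ndarray:
    hw = geometry.body_width_px / 2.0 * margin
    hh = geometry.body_height_px / 2.0 * margin
    return np.array([[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]])


@dataclass
class RenderedStack:
    """Phantom frames plus the tracker inputs derived from them."""

    frames: np.ndarray  # (n_frames, H, W) uint8
    templates: list[dict]  # median-frame polygons, one per vertebra
    reference_frame_index: int
    centers: np.ndarray  # (n_frames, n_vert, 2) world (x, y)
    angles: np.ndarray  # (n_frames, n_vert) degrees
    out_of_bounds: list[tuple[int, str]]  # (frame, vertebra) flags

    @property
    def any_out_of_bounds(self) -> bool:
        return bool(self.out_of_bounds)


def render_frames(
    recording: GroundTruthRecording,
    geometry: GeometryConfig | None = None,
    seed: int = 0,
) -> RenderedStack:
    """Render the recording as a grayscale cine stack.

    Each vertebra is a textured quadrilateral -- a bright cortical rim plus
    an internal trabecular speckle pattern fixed in body coordinates, so
    image gradients are informative and rotate with the body -- drawn at
    its ground-truth pose.  The background carries fixed-pattern noise
    (identical across frames), so a motionless recording renders to
    pixel-identical frames.  Returns the median-frame polygon outlines as
    tracker input.  Deterministic for a fixed seed.  Vertebrae whose
    corners leave the canvas raise a warning and are flagged.
    """
    from scipy.ndimage import gaussian_filter, map_coordinates

    geometry = geometry if geometry is not None else GeometryConfig()
    rng = np.random.default_rng(seed)
    h, w = geometry.image_shape
    n_frames, n_vert = recording.angles.shape
    centers, angles = vertebra_world_poses(recording, geometry)

    corners_body = _body_corners(geometry)
    hw = geometry.body_width_px / 2.0
    hh = geometry.body_height_px / 2.0

    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    out_of_bounds: list[tuple[int, str]] = []

    # per-vertebra trabecular speckle, ~1 texel per pixel, feature scale ~3 px
    spk_shape = (max(int(2 * hh), 8), max(int(2 * hw), 8))
    speckles = []
    for j in range(n_vert):
        s = gaussian_filter(
            np.random.default_rng((seed * 9973 + j) % (2**31 - 1)).standard_normal(spk_shape),
            1.2,
        )
        speckles.append(s / (3.0 * s.std()))

    background = np.full((h, w), geometry.background_level, dtype=float)
    noise = rng.normal(0.0, geometry.noise_sd, size=(h, w))
    if geometry.background_smooth_px > 0:
        # soft-tissue-like mottle: smooth, weak gradients
        noise = gaussian_filter(noise, geometry.background_smooth_px)
        sd = noise.std()
        if sd > 0:
            noise *= geometry.noise_sd / sd
    background += noise

    for t in range(n_frames):
        img = background.copy()
        for j in range(n_vert):
            c = centers[t, j]
            ang = angles[t, j]
            world_corners = c + corners_body @ _rot(ang).T
            if (
                world_corners[:, 0].min() < 0
                or world_corners[:, 1].min() < 0
                or world_corners[:, 0].max() > w - 1
                or world_corners[:, 1].max() > h - 1
            ):
                label = recording.vertebra_labels[j]
                warnings.warn(
                    f"vertebra {label} outside image bounds at frame {t}",
                    stacklevel=2,
                )
                out_of_bounds.append((t, label))
            # inverse-map pixels in the bounding box into the body frame
            x0 = max(int(np.floor(world_corners[:, 0].min())) - 1, 0)
            x1 = min(int(np.ceil(world_corners[:, 0].max())) + 2, w)
            y0 = max(int(np.floor(world_corners[:, 1].min())) - 1, 0)
            y1 = min(int(np.ceil(world_corners[:, 1].max())) + 2, h)
            if x0 >= x1 or y0 >= y1:
                continue
            px = xx[y0:y1, x0:x1] - c[0]
            py = yy[y0:y1, x0:x1] - c[1]
            rinv = _rot(-ang)
            u = rinv[0, 0] * px + rinv[0, 1] * py
            v = rinv[1, 0] * px + rinv[1, 1] * py
            inside = (np.abs(u) <= hw) & (np.abs(v) <= hh)
            rim = inside & (
                (np.abs(u) > hw - geometry.rim_width_px)
                | (np.abs(v) > hh - geometry.rim_width_px)
            )
            rows = (v + hh) * (spk_shape[0] - 1) / (2 * hh)
            cols = (u + hw) * (spk_shape[1] - 1) / (2 * hw)
            spk = map_coordinates(
                speckles[j], [rows.ravel(), cols.ravel()], order=1, mode="nearest"
            ).reshape(u.shape)
            tex = geometry.body_level + geometry.texture_amplitude * spk
            patch = img[y0:y1, x0:x1]
            patch[inside] = tex[inside]
            patch[rim] = geometry.rim_level
        if geometry.psf_sigma_px > 0:
            img = gaussian_filter(img, geometry.psf_sigma_px)
        if geometry.occlusion_band is not None:
            # overprojected pelvic/abdominal tissue: washes out contrast and
            # fluctuates frame to frame (breathing, bowel gas)
            r0, r1 = geometry.occlusion_band
            img[r0:r1, :] = (
                (1.0 - geometry.occlusion_alpha) * img[r0:r1, :]
                + geometry.occlusion_alpha * geometry.occlusion_level
            )
            if geometry.occlusion_noise_sd > 0:
                img[r0:r1, :] += rng.normal(
                    0.0, geometry.occlusion_noise_sd, size=img[r0:r1, :].shape
                )
        frames[t] = np.clip(img * 255.0, 0, 255).astype(np.uint8)

    ref = n_frames // 2
    corners_tpl = _body_corners(geometry, geometry.template_margin)
    templates = []
    for j in range(n_vert):
        poly = centers[ref, j] + corners_tpl @ _rot(angles[ref, j]).T
        templates.append(
            {
                "vertebra_label": recording.vertebra_labels[j],
                "reference_frame_index": int(ref),
                "polygon": [[float(x), float(y)] for x, y in poly],
            }
        )
    return RenderedStack(
        frames=frames,
        templates=templates,
        reference_frame_index=ref,
        centers=centers,
        angles=angles,
        out_of_bounds=out_of_bounds,
    )


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------


def write_bundle(stack: RenderedStack, recording: GroundTruthRecording, outdir) -> dict:
    """Write frames (multi-page TIFF), template JSON and ground-truth CSV.

    Ground-truth CSV columns: frame, vertebra, angle_deg (absolute sagittal
    angle), tx_px, ty_px (body-centre displacement from the median frame).
    Returns the paths written.
    """
    import pathlib

    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tiff_path = outdir / "frames.tif"
    tifffile.imwrite(tiff_path, stack.frames)

    tpl_path = outdir / "templates.json"
    tpl_path.write_text(json.dumps(stack.templates, indent=2))

    ref = stack.reference_frame_index
    n_frames, n_vert = stack.angles.shape
    rows = []
    for t in range(n_frames):
        for j in range(n_vert):
            rows.append(
                {
                    "frame": t,
                    "vertebra": recording.vertebra_labels[j],
                    "angle_deg": stack.angles[t, j],
                    "tx_px": stack.centers[t, j, 0] - stack.centers[ref, j, 0],
                    "ty_px": stack.centers[t, j, 1] - stack.centers[ref, j, 1],
                }
            )
    gt_path = outdir / "ground_truth.csv"
    pd.DataFrame(rows).to_csv(gt_path, index=False)
    return {"frames": tiff_path, "templates": tpl_path, "ground_truth": gt_path}
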