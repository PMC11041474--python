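"""Shared fixtures: synthetic recordings and rendered phantom stacks.

The rendered-and-tracked fixtures are session-scoped because tracking a
phantom takes tens of seconds; several tests interrogate the same result.
"""

from __future__ import annotations

import numpy as np
import pytest

from lumbarseq import tracking as trk
from lumbarseq.synth import (
    GeometryConfig,
    GroundTruthRecording,
    MotionProtocol,
    SegmentKinematicsSpec,
    SegmentSpec,
    generate_kinematics,
    render_frames,
)


@pytest.fixture(scope="session")
def default_recording():
    return generate_kinematics(seed=0)


@pytest.fixture(scope="session")
def noiseless_recording():
    from lumbarseq.synth import default_segment_specs

    spec = SegmentKinematicsSpec(default_segment_specs(noise_sd_deg=0.0))
    return generate_kinematics(spec, seed=0)


def rigid_rotation_recording(n_frames: int = 51, deg_per_frame: float = 0.5):
    """Two-body recording: the upper body rotates rigidly, the lower is static."""
    proto = MotionProtocol(n_frames=n_frames)
    upper = deg_per_frame * (np.arange(n_frames) - n_frames // 2)
    angles = np.column_stack([upper, np.zeros(n_frames)])
    rel = angles[:, 0:1] - angles[:, 1:2]
    inc = np.diff(rel, axis=0)
    # the spec here is only carried as metadata; keep the range positive
    spec = SegmentKinematicsSpec(
        {"AB": SegmentSpec(max(abs(deg_per_frame) * (n_frames - 1), 1.0), 0.5, 0.2, 0.0)}
    )
    return GroundTruthRecording(
        protocol=proto,
        spec=spec,
        vertebra_labels=("A", "B"),
        segment_labels=("AB",),
        angles=angles,
        segment_increments_true=inc,
        segment_increments_reported=inc.copy(),
        cumulative_coordinate=np.linspace(0, 1, n_frames),
        peak_sequence_true=("AB",),
    )


@pytest.fixture(scope="session")
def rigid_stack():
    """Rendered phantom rotating rigidly at 0.5 deg/frame."""
    rec = rigid_rotation_recording()
    geom = GeometryConfig(
        image_shape=(300, 300),
        body_width_px=90,
        body_height_px=60,
        disc_gap_px=30,
        noise_sd=0.01,
    )
    return render_frames(rec, geom, seed=5)


@pytest.fixture(scope="session")
def rigid_track(rigid_stack):
    """Tracking result for the rotating body of the rigid phantom."""
    templates = trk.templates_from_json(rigid_stack.templates)
    assert templates[0].vertebra_label == "A"
    return trk.track_vertebra(rigid_stack.frames, templates[0])


def small_column_geometry(**overrides) -> GeometryConfig:
    defaults = dict(
        image_shape=(300, 240),
        body_width_px=42,
        body_height_px=26,
        disc_gap_px=12,
        noise_sd=0.01,
    )
    defaults.update(overrides)
    return GeometryConfig(**defaults)
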