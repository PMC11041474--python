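"""Pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .pattern import CANONICAL_PATTERN, DEFAULT_LAST_PHASE_FRACTION, DEFAULT_SIGMA, PEAK_THRESHOLD_DEG
from .synth import SEGMENTS, ValidationError


@dataclass
class PipelineConfig:
    """Every tunable of the simulate -> track -> analyse pipeline.

    All numeric defaults used in reports trace back to a field here.
    """

    # protocol
    duration_s: float = 14.0
    frame_rate_hz: float = 7.5
    n_frames: int = 104
    neutral_start: float = 0.5
    phase_fractions: tuple[float, float, float] = (0.2, 0.4, 0.4)
    # tracker
    max_rotation_per_frame_deg: float = 6.0
    max_translation_per_frame_px: float = 20.0
    pyramid_levels: int = 3
    epsilon: float | None = None  # None = 10% of template gradient-magnitude median
    score_floor: float = 0.05
    # analysis
    smoothing_sigma: float = DEFAULT_SIGMA
    peak_threshold_deg: float = PEAK_THRESHOLD_DEG
    last_phase_fraction: float = DEFAULT_LAST_PHASE_FRACTION
    full_block: tuple[str, ...] = SEGMENTS  # cumulative axis for the full column
    pattern_block: tuple[str, ...] = ("L1L2", "L2L3", "L3L4")  # upper lumbar
    canonical_pattern: tuple[str, ...] = CANONICAL_PATTERN
    # reliability
    icc_variant: str = "consistency"
    # simulation
    noise_sd_deg: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.last_phase_fraction <= 1.0:
            raise ValidationError("last_phase_fraction must lie in (0, 1]")
        if self.peak_threshold_deg < 0:
            raise ValidationError("peak_threshold_deg must be >= 0")
        if self.icc_variant not in ("consistency", "agreement"):
            raise ValidationError("icc_variant must be 'consistency' or 'agreement'")

    def to_yaml(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        for k in ("phase_fractions", "full_block", "pattern_block", "canonical_pattern"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)
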