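"""Inter-rater reliability of tracked segmental rotations.

Two analysts independently re-measure the same intervertebral rotation
sequences; agreement is quantified with the two-way mixed intraclass
correlation coefficient.  The default form is ICC(3,1): single measure,
consistency, raters fixed --

    ICC(3,1) = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)

from the two-way ANOVA decomposition over n targets x k raters.  An ICC
above 0.60 is considered adequate.  The absolute-agreement single-measure
variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import ValidationError

ADEQUACY_THRESHOLD = 0.60


@dataclass
class RatingsTable:
    """n measurement targets rated by k raters; no missing cells."""

    values: np.ndarray  # (n, k) degrees
    target_ids: tuple | None = None
    rater_ids: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("ratings must be a 2-D (targets x raters) table")
        n, k = self.values.shape
        if n < 3:
            raise ValidationError("need at least 3 targets")
        if k < 2:
            raise ValidationError("need at least 2 raters")
        if not np.isfinite(self.values).all():
            raise ValidationError("ratings table contains missing/non-finite cells")


def _two_way_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the two-way crossed ANOVA."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_error


def icc_two_way_mixed(
    table: RatingsTable | np.ndarray, variant: str = "consistency"
) -> float:
    """Two-way mixed, single-measure intraclass correlation.

    ``variant='consistency'`` gives ICC(3,1); ``'agreement'`` gives the
    absolute-agreement single-measure form, which additionally penalises
    systematic rater offsets.  With zero between-target variance the value
    follows the formula and may be <= 0 or NaN.
    """
    if not isinstance(table, RatingsTable):
        table = RatingsTable(np.asarray(table))
    values = table.values
    n, k = values.shape
    ms_rows, ms_cols, ms_error = _two_way_mean_squares(values)
    if variant == "consistency":
        denom = ms_rows + (k - 1) * ms_error
    elif variant == "agreement":
        denom = ms_rows + (k - 1) * ms_error + (k / n) * (ms_cols - ms_error)
    else:
        raise ValidationError(f"unknown ICC variant: {variant!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        return float((ms_rows - ms_error) / denom)


@dataclass
class ICCReport:
    """ICC of one segment in one recording."""

    segment_label: str
    recording_id: str
    icc_value: float

    @property
    def adequate(self) -> bool:
        return self.icc_value > ADEQUACY_THRESHOLD


def segment_icc_summary(reports: list[ICCReport]) -> pd.DataFrame:
    """Per-segment table of ICC values with the across-recording mean.

    Means are rounded to 3 decimals for display; a segment is adequate only
    if its mean exceeds 0.60.  Mirrors the standard segment-by-recording
    reliability table layout.
    """
    if not reports:
        raise ValidationError("no ICC reports supplied")
    df = pd.DataFrame(
        {
            "segment": [r.segment_label for r in reports],
            "recording": [r.recording_id for r in reports],
            "icc": [r.icc_value for r in reports],
        }
    )
    wide = df.pivot(index="segment", columns="recording", values="icc")
    if wide.isna().any().any():
        raise ValidationError("every segment needs a value for every recording")
    # preserve first-appearance segment order (anatomical, as supplied)
    order = list(dict.fromkeys(df["segment"]))
    wide = wide.loc[order]
    wide["mean"] = wide.mean(axis=1).round(3)
    wide["adequate"] = wide["mean"] > ADEQUACY_THRESHOLD
    return wide


def icc_from_rater_series(
    series_a: np.ndarray, series_b: np.ndarray, variant: str = "consistency"
) -> float:
    """ICC of one segment's frame-pair rotation series measured by two raters."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("the two raters must rate the same targets")
    return icc_two_way_mixed(np.column_stack([a, b]), variant=variant)
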