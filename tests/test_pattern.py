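"""Gaussian smoothing, peak detection and sequence classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumbarseq import pattern as pat
from lumbarseq.kinematics import CumulativeAxis, SegmentSeries
from lumbarseq.synth import ValidationError


def brute_force_smooth(values, sigma):
    """Direct-summation Gaussian convolution with symmetric (reflected) padding."""
    values = np.asarray(values, dtype=float)
    radius = max(int(np.ceil(4.0 * sigma)), 1)
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(values, radius, mode="symmetric")
    out = np.empty(len(values))
    for i in range(len(values)):
        acc = 0.0
        for j, kj in enumerate(kernel):
            acc += kj * padded[i + j]
        out[i] = acc
    return out


def brute_force_peaks(y, threshold):
    """Exhaustive scan for strict local maxima with plateau-midpoint resolution."""
    peaks = []
    n = len(y)
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                mid = (i + j) // 2
                if y[mid] >= threshold:
                    peaks.append(mid)
                i = j + 1
                continue
            i = j + 1
        else:
            i += 1
    return peaks


def curve(y, x=None, label="L3L4", sigma=2.0, valid=True):
    y = np.asarray(y, dtype=float)
    x = np.arange(len(y), dtype=float) if x is None else np.asarray(x, float)
    return pat.ContributionCurve(label, x, y, sigma, valid=valid)


class TestGaussianSmooth:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(
            pat.gaussian_smooth(np.full(20, 3.7), sigma=2.0), np.full(20, 3.7),
            atol=1e-12,
        )

    def test_impulse_preserves_mass_and_symmetry(self):
        y = np.zeros(41)
        y[20] = 1.0
        out = pat.gaussian_smooth(y, sigma=1.0)
        assert abs(out.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)

    @pytest.mark.parametrize("sigma", [0.8, 2.0, 3.5])
    def test_matches_direct_convolution(self, sigma):
        rng = np.random.default_rng(42)
        y = rng.normal(size=50)
        np.testing.assert_allclose(
            pat.gaussian_smooth(y, sigma), brute_force_smooth(y, sigma), atol=1e-12
        )

    def test_short_or_invalid_input_rejected(self):
        with pytest.raises(ValidationError):
            pat.gaussian_smooth(np.ones(2), 1.0)
        with pytest.raises(ValidationError):
            pat.gaussian_smooth(np.ones(10), 0.0)


class TestDetectPeaks:
    def test_single_retained_peak(self):
        events = pat.detect_peaks(curve([0.1, 0.5, 0.1]))
        assert len(events) == 1
        assert events[0].height == 0.5
        assert events[0].index == 1

    def test_subthreshold_maximum_discarded(self):
        assert pat.detect_peaks(curve([0.1, 0.25, 0.1])) == []

    def test_plateau_resolved_to_midpoint(self):
        events = pat.detect_peaks(curve([0.0, 0.6, 0.6, 0.6, 0.0]))
        assert [e.index for e in events] == [2]

    def test_endpoints_never_peaks(self):
        assert pat.detect_peaks(curve([1.0, 0.5, 0.4, 0.9])) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        # quantized values provoke plateaus
        y = np.round(rng.normal(0.3, 0.3, size=60), 1)
        events = pat.detect_peaks(curve(y), threshold=0.3)
        assert [e.index for e in events] == brute_force_peaks(y, 0.3)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(-5, 10), min_size=3, max_size=50))
    def test_threshold_monotonicity(self, raw):
        """Raising the threshold never increases the number of retained peaks."""
        y = np.array(raw, dtype=float) / 10.0
        c = curve(y)
        counts = [len(pat.detect_peaks(c, thr)) for thr in (0.0, 0.2, 0.4, 0.8)]
        assert counts == sorted(counts, reverse=True)


def single_peak_curves(positions, height=1.0, width=40, x_max=20.0):
    """One Gaussian-bump curve per segment, peaking at the given x positions."""
    x = np.linspace(0.0, x_max, width)
    out = {}
    for label, pos in positions.items():
        y = height * np.exp(-0.5 * ((x - pos) / 1.2) ** 2)
        out[label] = pat.ContributionCurve(label, x, y, 2.0)
    return out


class TestClassifySequence:
    def test_canonical_order_matches(self):
        curves = single_peak_curves({"L3L4": 14.0, "L2L3": 16.0, "L1L2": 18.0})
        c = pat.classify_sequence(curves, "extension2")
        assert c.matches_canonical
        assert [p.segment_label for p in c.ordered_peaks] == ["L3L4", "L2L3", "L1L2"]

    def test_swapped_order_fails(self):
        curves = single_peak_curves({"L3L4": 16.0, "L2L3": 14.0, "L1L2": 18.0})
        assert not pat.classify_sequence(curves, "extension2").matches_canonical

    def test_peak_outside_last_phase_window_fails(self):
        curves = single_peak_curves({"L3L4": 5.0, "L2L3": 16.0, "L1L2": 18.0})
        assert not pat.classify_sequence(curves, "extension2").matches_canonical

    def test_position_tie_breaks_toward_non_match(self):
        x = np.linspace(0.0, 20.0, 41)
        y = np.zeros(41)
        y[36] = 1.0  # same position for two segments
        curves = {
            "L3L4": pat.ContributionCurve("L3L4", x, y.copy(), 2.0),
            "L2L3": pat.ContributionCurve("L2L3", x, y.copy(), 2.0),
            "L1L2": pat.ContributionCurve("L1L2", x, np.roll(y, 2), 2.0),
        }
        assert not pat.classify_sequence(curves, "extension2").matches_canonical

    def test_invalid_curve_excludes_recording(self):
        curves = single_peak_curves({"L3L4": 14.0, "L2L3": 16.0, "L1L2": 18.0})
        curves["L3L4"].valid = False
        c = pat.classify_sequence(curves, "extension2")
        assert c.excluded
        assert not c.matches_canonical
        assert "L3L4" in c.exclusion_reason

    def test_time_reversal_reverses_peak_order(self):
        """A reversed extension phase shows the mirrored contribution sequence."""
        curves = single_peak_curves({"L3L4": 14.0, "L2L3": 16.0, "L1L2": 18.0})
        reversed_curves = {
            lab: pat.ContributionCurve(
                lab, c.x[-1] - c.x[::-1], c.y[::-1], c.smoothing_sigma
            )
            for lab, c in curves.items()
        }
        fwd = pat.classify_sequence(curves, "extension2", last_phase_fraction=1.0)
        rev = pat.classify_sequence(reversed_curves, "flexion", last_phase_fraction=1.0)
        assert [p.segment_label for p in rev.ordered_peaks] == [
            p.segment_label for p in fwd.ordered_peaks
        ][::-1]
        assert not rev.matches_canonical

    def test_missing_canonical_segment_rejected(self):
        curves = single_peak_curves({"L3L4": 14.0, "L2L3": 16.0})
        with pytest.raises(ValidationError):
            pat.classify_sequence(curves, "extension2")


class TestSmoothCurve:
    def test_oracle_equivalence_via_series(self):
        rng = np.random.default_rng(3)
        inc = rng.normal(0.5, 0.4, 60)
        s = SegmentSeries("L3L4", inc, np.ones(60, bool))
        cum = CumulativeAxis(("L3L4",), np.cumsum(inc))
        c = pat.smooth_curve(s, cum, sigma=2.0)
        np.testing.assert_allclose(c.y, brute_force_smooth(inc, 2.0), atol=1e-12)

    def test_flip_sign_negates_and_reverses_direction(self):
        inc = -np.ones(10)
        s = SegmentSeries("L3L4", inc, np.ones(10, bool))
        cum = CumulativeAxis(("L3L4",), np.cumsum(inc))
        c = pat.smooth_curve(s, cum, sigma=1.0, flip_sign=True)
        assert (c.y > 0).all()
        assert c.x[0] == 0.0 and c.x[-1] > 0


class TestConsistencySummary:
    @staticmethod
    def table(rows):
        return pd.DataFrame(
            rows, columns=["participant", "time_point", "matches_canonical", "excluded"]
        )

    def test_eight_of_ten_is_80_percent(self):
        rows = [(f"P{i}", "T1", i > 2, False) for i in range(1, 11)]
        s = pat.consistency_summary(self.table(rows))
        assert s["per_time_point"]["T1"]["fraction_percent"] == pytest.approx(80.0)
        assert s["cohort_consistent"]

    def test_fifteen_of_twentyone_rounds_to_71(self):
        rows = [(f"P{i}", "T1", i > 2, False) for i in range(1, 11)]
        rows += [(f"P{i}", "T2", i > 4, False) for i in range(1, 12)]
        s = pat.consistency_summary(self.table(rows))
        assert s["n_analyzable"] == 21
        assert s["n_canonical"] == 15
        assert round(s["overall_percent"]) == 71

    def test_all_canonical(self):
        rows = [(f"P{i}", tp, True, False) for i in range(1, 6) for tp in ("T1", "T2")]
        s = pat.consistency_summary(self.table(rows))
        assert s["overall_percent"] == 100.0
        assert s["consistent_participants"] == [f"P{i}" for i in range(1, 6)]

    def test_excluded_recordings_counted_not_analyzed(self):
        rows = [("P1", "T1", False, True)] + [
            (f"P{i}", "T1", True, False) for i in range(2, 5)
        ]
        s = pat.consistency_summary(self.table(rows))
        assert s["n_excluded"] == 1
        assert s["per_time_point"]["T1"]["n"] == 3

    def test_participant_missing_a_time_point_not_consistent(self):
        rows = [("P1", "T1", True, False), ("P1", "T2", True, False),
                ("P2", "T1", True, False)]
        s = pat.consistency_summary(self.table(rows))
        assert s["consistent_participants"] == ["P1"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            pat.consistency_summary(self.table([]))
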