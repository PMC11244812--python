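import numpy as np
import pytest
from hypothesis import given, strategies as st

import catrace as ct
from catrace.calibration import injected_transient_trace, two_peak_trace
from catrace.core import CatraceError, StageError, TraceMatrix, TransientEvent
from catrace.events import DetectionParams, _envelopes


def sd_trace(values, fs=10.0):
    return TraceMatrix(np.asarray(values, dtype=float), fs, stage="standardized")


class TestMinDuration:
    @pytest.mark.parametrize("amp, expected", [
        (0.5, 0.0),                       # at the baseline level: zero decay
        (1.0, 0.2),                       # exactly one half-life 1.0 -> 0.5
        (3.0, 0.2 * np.log2(6.0)),        # ~0.517 s
    ])
    def test_decay_time_values(self, amp, expected):
        assert ct.min_duration(amp) == pytest.approx(expected, abs=1e-12)

    def test_below_baseline_rejected(self):
        with pytest.raises(CatraceError):
            ct.min_duration(0.3)

    @given(a=st.floats(0.5, 50.0), b=st.floats(0.5, 50.0))
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert ct.min_duration(lo) <= ct.min_duration(hi)
        assert ct.min_duration(a) >= 0.0


class TestDetect:
    def test_flat_trace_yields_nothing(self):
        assert ct.detect_transients(sd_trace(np.zeros(100))) == []

    def test_subthreshold_peak_rejected(self):
        trace = injected_transient_trace(2.9)
        assert ct.detect_transients(trace) == []

    def test_ideal_kernel_transient_detected(self):
        """A noise-free 5 SD transient with t_half decay gives one event."""
        lam = 2.0 ** (-1.0 / 2.0)          # half-life 0.2 s at 10 Hz
        x = np.zeros(100)
        x[30:60] = 5.0 * lam ** np.arange(30)
        events = ct.detect_transients(sd_trace(x))
        assert len(events) == 1
        e = events[0]
        assert e.amplitude_sd == pytest.approx(5.0, abs=0.01)
        assert e.peak_frame == 30
        # envelope: frames 30..36 are >= 0.5 (5 * 0.7071^6 = 0.625)
        assert (e.onset_frame, e.offset_frame) == (30, 37)

    def test_short_transient_fails_duration_criterion(self):
        """A 5 SD blip decaying much faster than t_half is rejected."""
        x = np.zeros(100)
        x[30] = 5.0
        assert ct.detect_transients(sd_trace(x)) == []

    def test_stage_enforced(self):
        raw = TraceMatrix(np.zeros((50, 1)), 10.0, stage="raw")
        with pytest.raises(StageError):
            ct.detect_transients(raw)

    def test_translation_invariance(self):
        trace = injected_transient_trace(5.0)
        x = trace.values[:, 0]
        shifted = np.concatenate([np.zeros(37), x])
        ev0 = ct.detect_transients(sd_trace(x))
        ev1 = ct.detect_transients(sd_trace(shifted))
        assert len(ev0) == len(ev1) == 1
        assert ev1[0].onset_frame - ev0[0].onset_frame == 37
        assert ev1[0].amplitude_sd == ev0[0].amplitude_sd


class TestSplitMultipeak:
    def test_single_peak_unchanged(self):
        trace = injected_transient_trace(5.0)
        ev_nosplit = ct.detect_transients(trace, split_peaks=False)
        ev_split = ct.detect_transients(trace, split_peaks=True)
        assert ev_split == ev_nosplit

    def test_two_well_separated_peaks_split_at_valley(self):
        """5 SD peaks 2 s apart over a 1 SD valley become two events."""
        trace = two_peak_trace(4.0, peak1_sd=5.0, peak2_sd=5.0)
        events = ct.detect_transients(trace)
        assert len(events) == 2
        a, b = events
        assert a.offset_frame == b.onset_frame        # split at the valley
        valley = int(np.argmin(trace.values[a.peak_frame:b.peak_frame, 0]))
        assert a.offset_frame == a.peak_frame + valley
        assert a.amplitude_sd == pytest.approx(5.0)
        assert b.amplitude_sd == pytest.approx(5.0)

    def test_close_peaks_not_split(self):
        """Peaks 0.5 s apart stay one event (min distance 1 s)."""
        trace = two_peak_trace(4.0, peak1_sd=5.0, peak2_sd=5.0,
                               separation_s=0.5)
        assert len(ct.detect_transients(trace)) == 1

    def test_split_respects_distance_constraint(self):
        """No pair of split events has peaks closer than the min distance."""
        rng = np.random.default_rng(12)
        params = DetectionParams()
        for _ in range(20):
            x = np.maximum(0.0, rng.normal(1.0, 2.0, size=400))
            x = np.convolve(x, [0.4, 0.6, 0.4], mode="same")
            events = ct.detect_transients(sd_trace(x), params)
            dist = int(round(params.min_peak_distance_s * 10.0))
            for a, b in zip(events[:-1], events[1:]):
                if a.offset_frame == b.onset_frame:   # siblings of one envelope
                    assert b.peak_frame - a.peak_frame >= dist

    def test_split_matches_brute_force_peak_enumeration(self):
        """Retained peaks equal a brute-force prominence/distance filter."""
        rng = np.random.default_rng(21)
        params = DetectionParams()
        for _ in range(10):
            x = np.maximum(0.0, rng.normal(1.0, 2.0, size=300))
            x = np.convolve(x, [0.5, 1.0, 0.5], mode="same")
            for on, off in _envelopes(x, params.baseline_threshold_sd):
                seg = x[on:off]
                if seg.max() < params.amp_threshold_sd:
                    continue
                expected = brute_force_peaks(seg, params, fs=10.0)
                events = ct.detect_transients(sd_trace(x), params)
                got = [e.peak_frame - on for e in events
                       if on <= e.peak_frame < off]
                if got:  # envelope may fail the duration criterion entirely
                    assert got == expected


def brute_force_peaks(seg, params, fs):
    """Enumerate local maxima of the padded envelope, suppress neighbors
    closer than the distance (tallest first), then filter by topographic
    prominence computed from its definition."""
    pad = params.baseline_threshold_sd - 1.0
    y = np.concatenate([[pad], seg, [pad]])
    n = len(y)
    maxima = [i for i in range(1, n - 1) if y[i - 1] < y[i] > y[i + 1]]
    dist = int(round(params.min_peak_distance_s * fs))
    removed: set[int] = set()
    for i in sorted(maxima, key=lambda i: -y[i]):
        if i in removed:
            continue
        for j in maxima:
            if j != i and j not in removed and abs(j - i) < dist:
                removed.add(j)
    survivors = [i for i in maxima if i not in removed]

    def prominence(i):
        bases = []
        for step in (-1, 1):
            j, run_min = i + step, y[i]
            while 0 <= j < n and y[j] <= y[i]:
                run_min = min(run_min, y[j])
                j += step
            bases.append(run_min)
        return y[i] - max(bases)

    return [i - 1 for i in survivors
            if prominence(i) >= params.peak_prominence_sd]


class TestAucPerSec:
    def test_no_events_zero(self):
        assert ct.auc_per_sec(sd_trace(np.zeros(100)), []) == 0.0

    def test_rectangular_event(self):
        """2 SD for 1 s within a 10 s recording -> 0.2 SD*s/s."""
        x = np.zeros(100)
        x[10:20] = 2.0
        ev = TransientEvent("n0", 10, 20, 15, 2.0, 1.0)
        assert ct.auc_per_sec(sd_trace(x), [ev]) == pytest.approx(0.2)

    def test_doubling_duration_halves_value(self):
        x = np.zeros(100)
        x[10:20] = 2.0
        ev = TransientEvent("n0", 10, 20, 15, 2.0, 1.0)
        v100 = ct.auc_per_sec(sd_trace(x), [ev])
        v200 = ct.auc_per_sec(sd_trace(np.concatenate([x, np.zeros(100)])), [ev])
        assert v200 == pytest.approx(v100 / 2.0)

    def test_negative_excursions_rectified(self):
        x = np.full(100, -1.0)
        x[10:20] = 2.0
        ev = TransientEvent("n0", 8, 22, 15, 2.0, 1.4)
        assert ct.auc_per_sec(sd_trace(x), [ev]) == pytest.approx(0.2)

    def test_overlapping_events_rejected(self):
        x = np.zeros(100)
        a = TransientEvent("n0", 10, 20, 15, 2.0, 1.0)
        b = TransientEvent("n0", 15, 30, 20, 2.0, 1.5)
        with pytest.raises(CatraceError):
            ct.auc_per_sec(sd_trace(x), [a, b])

    def test_mixed_neurons_rejected(self):
        x = np.zeros((100, 2))
        a = TransientEvent("n0", 10, 20, 15, 2.0, 1.0)
        b = TransientEvent("n1", 30, 40, 35, 2.0, 1.0)
        with pytest.raises(CatraceError):
            ct.auc_per_sec(sd_trace(x), [a, b])


class TestEventRecovery:
    def test_f1_against_ground_truth(self, detection_session):
        """Detected events match simulated event times at F1 >= 0.9."""
        from conftest import event_f1
        session, std = detection_session
        assert event_f1(session, std) >= 0.9
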