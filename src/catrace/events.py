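"""Ca2+ transient event detection and per-neuron AUC/sec.

A candidate transient is a maximal run of frames where the standardized
trace stays at or above a 0.5 SD baseline level; it is kept as an event if
its peak reaches 3 SD and the envelope lasts at least the decay time from
the peak amplitude A back down to the 0.5 SD baseline A0 at the
indicator's half-life: ``t_half * log2(A / A0)``.  Large multi-peaked
envelopes are split into separate rising events at local maxima with
topographic prominence >= 2.5 SD spaced >= 1 s apart, cutting each
envelope at the valley between adjacent retained peaks.

AUC/sec — the per-neuron activity score used to rank populations — is the
rectified area under the trace inside detected events, normalized by the
recording duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import (CatraceError, InvalidConfigError, StageError, TraceMatrix,
                   TransientEvent)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for transient detection, all in SD units of the trace."""

    amp_threshold_sd: float = 3.0
    baseline_threshold_sd: float = 0.5
    t_half_s: float = 0.2
    peak_prominence_sd: float = 2.5
    min_peak_distance_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.amp_threshold_sd > self.baseline_threshold_sd > 0:
            raise InvalidConfigError(
                "need amp_threshold_sd > baseline_threshold_sd > 0")
        if not self.t_half_s > 0:
            raise InvalidConfigError("t_half_s must be > 0")
        if self.peak_prominence_sd <= 0 or self.min_peak_distance_s < 0:
            raise InvalidConfigError("bad peak-splitting parameters")


def min_duration(amplitude_sd: float, params: DetectionParams | None = None) -> float:
    """Minimum event duration in seconds for a transient of peak ``amplitude_sd``.

    The time for an exponential decay with half-life ``t_half_s`` to fall
    from A to the baseline level A0: ``t_half * log2(A / A0)``.  Zero at
    A = A0, monotone increasing in A.
    """
    params = params or DetectionParams()
    a0 = params.baseline_threshold_sd
    if amplitude_sd < a0:
        raise InvalidConfigError(
            f"amplitude {amplitude_sd} below the baseline level {a0}")
    return params.t_half_s * float(np.log2(amplitude_sd / a0))


def _envelopes(x: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs [on, off) where ``x >= threshold``."""
    above = x >= threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    onsets = list(np.flatnonzero(d == 1) + 1)
    offsets = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(x.size)
    return list(zip(onsets, offsets))


def _crossing_duration(x: np.ndarray, on: int, off: int, threshold: float,
                       fs: float) -> float:
    """Time the trace spends above ``threshold`` across envelope [on, off).

    The up- and down-crossings of the threshold fall inside the frames
    flanking the envelope; both are located by linear interpolation, so the
    duration estimates the continuous time above baseline rather than the
    (downward-biased) count of suprathreshold samples.
    """
    if on > 0:
        t_on = on - 1 + (threshold - x[on - 1]) / (x[on] - x[on - 1])
    else:
        t_on = 0.0
    if off < x.size:
        t_off = off - 1 + (x[off - 1] - threshold) / (x[off - 1] - x[off])
    else:
        t_off = float(x.size)
    return (t_off - t_on) / fs


def detect_transients(trace: TraceMatrix, params: DetectionParams | None = None,
                      split_peaks: bool = True) -> list[TransientEvent]:
    """Detect Ca2+ transient events on a trace in SD units.

    Accepts ``standardized`` or ``zscored`` traces.  Each suprathreshold
    envelope (trace >= ``baseline_threshold_sd`` until it returns below) is
    kept iff its peak is >= ``amp_threshold_sd`` and its onset-to-offset
    duration (between interpolated baseline crossings) meets
    :func:`min_duration` for that peak; kept envelopes are then optionally
    split at secondary peaks.  Events are returned sorted by
    (neuron, onset) and are non-overlapping within a neuron.
    """
    params = params or DetectionParams()
    if trace.stage not in ("standardized", "zscored"):
        raise StageError(
            f"detection needs a trace in SD units, got stage {trace.stage!r}")
    fs = trace.frame_rate_hz
    events: list[TransientEvent] = []
    for j in range(trace.n_neurons):
        x = trace.values[:, j]
        for on, off in _envelopes(x, params.baseline_threshold_sd):
            seg = x[on:off]
            amp = float(seg.max())
            if amp < params.amp_threshold_sd:
                continue
            dur = _crossing_duration(x, on, off, params.baseline_threshold_sd, fs)
            if dur < min_duration(amp, params):
                continue
            ev = TransientEvent(neuron_id=trace.neuron_ids[j],
                                onset_frame=on, offset_frame=off,
                                peak_frame=on + int(seg.argmax()),
                                amplitude_sd=amp, duration_s=dur)
            if split_peaks:
                events.extend(split_multipeak(ev, trace, params))
            else:
                events.append(ev)
    return events


def split_multipeak(event: TransientEvent, trace: TraceMatrix,
                    params: DetectionParams | None = None) -> list[TransientEvent]:
    """Split a multi-peaked envelope into separate rising events.

    Local maxima inside the envelope with topographic prominence >=
    ``peak_prominence_sd`` and pairwise spacing >= ``min_peak_distance_s``
    each become an event; boundaries are placed at the minimum of the trace
    between adjacent retained peaks (earliest frame on ties).  Always
    returns at least one event.
    """
    params = params or DetectionParams()
    fs = trace.frame_rate_hz
    j = trace.neuron_ids.index(event.neuron_id)
    seg = trace.values[event.onset_frame:event.offset_frame, j]
    # pad below the envelope floor so maxima at the envelope edges count as
    # peaks and their prominence is measured against the envelope interior
    pad = params.baseline_threshold_sd - 1.0
    padded = np.concatenate([[pad], seg, [pad]])
    distance = max(1, int(round(params.min_peak_distance_s * fs)))
    peaks, _ = find_peaks(padded, prominence=params.peak_prominence_sd,
                          distance=distance)
    peaks = peaks - 1  # undo padding offset
    if len(peaks) <= 1:
        return [event]
    out: list[TransientEvent] = []
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        valley = a + 1 + int(np.argmin(seg[a + 1:b + 1]))
        bounds.append(valley)
    bounds.append(len(seg))
    # each retained peak is the summit of its rising event; the sub-envelope
    # may contain taller non-retained maxima (suppressed by the distance
    # rule), so the event's peak is the retained peak itself
    for k, pk in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 1]
        out.append(TransientEvent(
            neuron_id=event.neuron_id,
            onset_frame=event.onset_frame + lo,
            offset_frame=event.onset_frame + hi,
            peak_frame=event.onset_frame + int(pk),
            amplitude_sd=float(seg[pk]),
            duration_s=(hi - lo) / fs))
    return out


def auc_per_sec(trace: TraceMatrix, events: list[TransientEvent],
                neuron_id: str | None = None) -> float:
    """Rectified area under the trace within events, per second of recording.

    Rectangle-rule integral of ``max(trace, 0)`` over each event's
    ``[onset, offset)`` in SD*s, summed and divided by the recording
    duration in seconds.  Returns 0.0 when there are no events.
    """
    if not events:
        return 0.0
    ids = {e.neuron_id for e in events}
    if neuron_id is None:
        if len(ids) > 1:
            raise CatraceError("events from multiple neurons; pass neuron_id")
        neuron_id = next(iter(ids))
    elif ids - {neuron_id}:
        raise CatraceError("events do not belong to the requested neuron")
    j = trace.neuron_ids.index(neuron_id)
    x = np.maximum(trace.values[:, j], 0.0)
    ordered = sorted(events, key=lambda e: e.onset_frame)
    for a, b in zip(ordered[:-1], ordered[1:]):
        if b.onset_frame < a.offset_frame:
            raise CatraceError(
                f"overlapping events at frames {b.onset_frame} < {a.offset_frame}")
    fs = trace.frame_rate_hz
    area = sum(x[e.onset_frame:e.offset_frame].sum() / fs for e in ordered)
    return float(area / trace.duration_s)


def events_to_frame(events: list[TransientEvent]) -> pd.DataFrame:
    """Tabulate events with one row per transient."""
    cols = ["neuron_id", "onset_frame", "offset_frame", "peak_frame",
            "amplitude_sd", "duration_s"]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events],
                        columns=cols)


def auc_table(trace: TraceMatrix, events: list[TransientEvent]) -> pd.Series:
    """AUC/sec for every neuron in the trace (0 for event-free neurons)."""
    by_neuron: dict[str, list[TransientEvent]] = {nid: [] for nid in trace.neuron_ids}
    for e in events:
        by_neuron[e.neuron_id].append(e)
    return pd.Series({nid: auc_per_sec(trace, evs, neuron_id=nid) if evs else 0.0
                      for nid, evs in by_neuron.items()}, name="auc_per_sec")
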