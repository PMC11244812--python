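"""Empirical localization of the detector's decision boundaries.

These routines verify, by bisection on noise-free synthetic inputs, where
the implemented detector actually switches behavior: the smallest peak
amplitude at which an isolated transient of ample duration is detected
(should sit at the 3 SD amplitude threshold), and the smallest topographic
prominence at which a secondary peak inside one envelope is split into its
own event (should sit at the 2.5 SD prominence threshold).
"""

from __future__ import annotations

import numpy as np

from .core import TraceMatrix
from .events import DetectionParams, detect_transients


def injected_transient_trace(peak_sd: float, frame_rate_hz: float = 10.0,
                             t_half_s: float = 0.2, plateau_frames: int = 20,
                             n_frames: int = 200) -> TraceMatrix:
    """Flat standardized trace with one noise-free transient of ``peak_sd``.

    The transient holds its peak for ``plateau_frames`` before decaying
    exponentially with ``t_half_s``, so its envelope duration comfortably
    exceeds the minimum-duration criterion at any amplitude of interest and
    detection hinges on amplitude alone.
    """
    x = np.zeros(n_frames)
    k0 = 50
    x[k0:k0 + plateau_frames] = peak_sd
    decay = peak_sd * np.exp2(-np.arange(1, 60) / (t_half_s * frame_rate_hz))
    k1 = k0 + plateau_frames
    n_tail = min(len(decay), n_frames - k1)
    x[k1:k1 + n_tail] = decay[:n_tail]
    return TraceMatrix(x[:, None], frame_rate_hz=frame_rate_hz, stage="standardized")


def two_peak_trace(prominence_sd: float, peak1_sd: float = 6.0,
                   peak2_sd: float = 5.0, separation_s: float = 2.0,
                   frame_rate_hz: float = 10.0) -> TraceMatrix:
    """Noise-free single envelope with two peaks ``separation_s`` apart.

    The valley between the peaks is placed at ``peak2_sd - prominence_sd``
    so the secondary peak's topographic prominence is exactly
    ``prominence_sd``.  The valley must stay at or above the 0.5 SD
    envelope floor, i.e. ``prominence_sd <= peak2_sd - 0.5``.
    """
    valley = peak2_sd - prominence_sd
    if valley < 0.5:
        raise ValueError("valley below the envelope floor; lower prominence_sd")
    fs = frame_rate_hz
    sep = int(round(separation_s * fs))
    p1, p2 = 10, 10 + sep
    n = p2 + 30
    x = np.zeros(n)
    mid = (p1 + p2) // 2
    x[p1 - 5:p1 + 1] = np.linspace(0.6, peak1_sd, 6)
    x[p1:mid + 1] = np.linspace(peak1_sd, valley, mid - p1 + 1)
    x[mid:p2 + 1] = np.linspace(valley, peak2_sd, p2 - mid + 1)
    x[p2:p2 + 9] = np.linspace(peak2_sd, 0.6, 9)
    return TraceMatrix(x[:, None], frame_rate_hz=fs, stage="standardized")


def _bisect_boundary(is_detected, lo: float, hi: float, tol: float) -> float:
    """Smallest value in [lo, hi] where ``is_detected`` flips to True."""
    if is_detected(lo) or not is_detected(hi):
        raise ValueError("bisection bracket does not straddle the boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_detected(mid):
            hi = mid
        else:
            lo = mid
    return hi


def detection_amplitude_threshold(params: DetectionParams | None = None,
                                  frame_rate_hz: float = 10.0,
                                  lo: float = 1.0, hi: float = 6.0,
                                  tol: float = 0.01) -> float:
    """Empirical amplitude threshold (SD) for isolated-transient detection."""
    params = params or DetectionParams()

    def detected(peak_sd: float) -> bool:
        trace = injected_transient_trace(peak_sd, frame_rate_hz,
                                         t_half_s=params.t_half_s)
        return len(detect_transients(trace, params)) >= 1

    return _bisect_boundary(detected, lo, hi, tol)


def split_prominence_threshold(params: DetectionParams | None = None,
                               frame_rate_hz: float = 10.0,
                               lo: float = 1.0, hi: float = 4.4,
                               tol: float = 0.01) -> float:
    """Empirical prominence threshold (SD) for secondary-peak splitting."""
    params = params or DetectionParams()

    def split(prominence_sd: float) -> bool:
        trace = two_peak_trace(prominence_sd, frame_rate_hz=frame_rate_hz)
        return len(detect_transients(trace, params)) >= 2

    return _bisect_boundary(split, lo, hi, tol)
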