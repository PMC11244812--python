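"""Raw fluorescence -> dF/F -> standardized -> deconvolved -> z-scored.

The baseline F0 is a sliding-window quantile: 500 frames (about 50 s at
10 Hz) with a per-neuron quantile cut-off between the bottom 10th
percentile and the median, lower for more active neurons so that frequent
transients do not inflate the baseline.  dF/F is (F - F0) / F0;
standardization subtracts the per-neuron median and divides by the sample
SD, putting traces in SD units for event detection.

Spike-rate estimation here is a first-order inverse filter against the
indicator's exponential decay kernel (half-life 200 ms for GCaMP6f),
half-wave rectified.  It is pluggable: any callable with the same
signature (for example a learned deconvolution model) can replace it in
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import (ConstantTraceError, DegenerateBaselineError,
                   InvalidConfigError, NonpositiveBaselineError, StageError,
                   TraceMatrix)


@dataclass(frozen=True)
class BaselineParams:
    """Sliding-baseline parameters.

    ``window_frames`` is the quantile window (500 frames ~ 50 s at 10 Hz);
    the quantile used per neuron is ``clamp(q_max - activity_fraction,
    q_min, q_max)`` where ``activity_fraction`` is the fraction of frames
    exceeding a rolling-median pre-pass by ``activity_probe_sd`` robust SDs.
    """

    window_frames: int = 500
    q_min: float = 0.10
    q_max: float = 0.50
    activity_probe_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.q_min <= self.q_max <= 0.5:
            raise InvalidConfigError("need 0 < q_min <= q_max <= 0.5")
        if self.window_frames < 3:
            raise InvalidConfigError("window_frames must be >= 3")

    def window_span_s(self, frame_rate_hz: float) -> float:
        """Length of the baseline window in seconds at a frame rate."""
        return self.window_frames / frame_rate_hz


def _quantile_of_sorted(sorted_rows: np.ndarray, q: float) -> np.ndarray:
    """Linear-interpolation quantile of each pre-sorted row."""
    w = sorted_rows.shape[1]
    pos = q * (w - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, w - 1)
    frac = pos - lo
    return sorted_rows[:, lo] * (1.0 - frac) + sorted_rows[:, hi] * frac


def _rolling_from_sorted(x: np.ndarray, window: int, q: float,
                         sorted_windows: np.ndarray | None) -> np.ndarray:
    """Rolling quantile given optionally pre-sorted interior windows."""
    n = x.size
    half = window // 2
    out = np.empty(n)
    if sorted_windows is not None:
        out[half:half + n - window + 1] = _quantile_of_sorted(sorted_windows, q)
        lo_edge = range(half)
        hi_edge = range(half + n - window + 1, n)
    else:
        lo_edge = range(n)
        hi_edge = range(0)
    for t in lo_edge:
        out[t] = np.quantile(x[:t - half + window], q)
    for t in hi_edge:
        out[t] = np.quantile(x[max(0, t - half):], q)
    return out


def rolling_quantile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Quantile of the ``window`` frames centered on each frame.

    The window for frame ``t`` is ``[t - window//2, t - window//2 + window)``
    intersected with the trace (truncated, not padded, at the edges).
    Quantiles interpolate linearly between order statistics.
    """
    x = np.asarray(x, dtype=float)
    sw = (np.sort(sliding_window_view(x, window), axis=1)
          if x.size >= window else None)
    return _rolling_from_sorted(x, window, q, sw)


def sliding_baseline(trace: TraceMatrix, params: BaselineParams | None = None
                     ) -> TraceMatrix:
    """Per-neuron sliding-window quantile baseline F0 of a raw trace.

    A rolling-median pre-pass estimates how active each neuron is; the
    activity fraction then lowers the baseline quantile from the median
    (silent neurons) toward the 10th percentile (busy neurons), clamped to
    ``[q_min, q_max]``.
    """
    params = params or BaselineParams()
    if trace.stage != "raw":
        raise StageError(f"sliding_baseline expects a raw trace, got {trace.stage!r}")
    w = min(params.window_frames, trace.n_frames)
    f0 = np.empty_like(trace.values)
    for j in range(trace.n_neurons):
        x = trace.values[:, j]
        # sort each window once; both the median pre-pass and the final
        # quantile interpolate from the same sorted windows
        sw = (np.sort(sliding_window_view(x, w), axis=1)
              if x.size >= w else None)
        provisional = _rolling_from_sorted(x, w, 0.5, sw)
        resid = x - provisional
        mad = np.median(np.abs(resid - np.median(resid)))
        robust_sd = 1.4826 * mad
        active = np.mean(x > provisional + params.activity_probe_sd * robust_sd)
        q = float(np.clip(params.q_max - active, params.q_min, params.q_max))
        f0[:, j] = _rolling_from_sorted(x, w, q, sw)
    if np.any(f0 <= 0):
        raise NonpositiveBaselineError(
            "baseline is not strictly positive; raw trace units are invalid for dF/F")
    return trace.with_values(f0, stage="raw")


def compute_dff(trace: TraceMatrix, f0: TraceMatrix) -> TraceMatrix:
    """dF/F0 = (F - F0) / F0, elementwise."""
    if trace.values.shape != f0.values.shape:
        raise InvalidConfigError("trace and baseline shapes differ")
    if np.any(f0.values <= 0):
        raise NonpositiveBaselineError("baseline must be strictly positive")
    return trace.with_values((trace.values - f0.values) / f0.values, stage="dff")


def standardize(trace: TraceMatrix) -> TraceMatrix:
    """Per neuron: subtract the median, divide by the sample SD (ddof=1)."""
    if trace.stage != "dff":
        raise StageError(f"standardize expects a dff trace, got {trace.stage!r}")
    med = np.median(trace.values, axis=0)
    sd = np.std(trace.values, axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [trace.neuron_ids[j] for j in np.flatnonzero(sd == 0)]
        raise ConstantTraceError(f"zero variance for neurons {bad}")
    return trace.with_values((trace.values - med) / sd, stage="standardized")


def decay_factor(t_half_s: float, frame_rate_hz: float) -> float:
    """Per-frame multiplicative decay of an exponential kernel."""
    return float(2.0 ** (-1.0 / (t_half_s * frame_rate_hz)))


def inverse_filter(values: np.ndarray, lam: float) -> np.ndarray:
    """Invert a causal exponential kernel: y(t) = x(t) - lam * x(t-1).

    Convolving the output with the kernel ``lam**t`` recovers the input
    exactly (assuming the signal is zero before frame 0).
    """
    y = np.array(values, dtype=float)
    y[1:] -= lam * values[:-1]
    return y


def deconvolve_standin(trace: TraceMatrix, t_half_s: float = 0.2) -> TraceMatrix:
    """Half-wave-rectified inverse filter against the indicator kernel.

    A simple recursive stand-in for learned spike inference: each frame's
    excess over the decayed previous frame is attributed to new activity,
    negative residuals (noise below the decay curve) are clipped to zero.
    """
    if not t_half_s > 0:
        raise InvalidConfigError("t_half_s must be > 0")
    if trace.stage != "standardized":
        raise StageError(f"deconvolve expects a standardized trace, got {trace.stage!r}")
    lam = decay_factor(t_half_s, trace.frame_rate_hz)
    y = inverse_filter(trace.values, lam)
    return trace.with_values(np.maximum(y, 0.0), stage="deconvolved")


def zscore_activity_masked(trace: TraceMatrix, threshold_sd: float = 3.0,
                           max_iter: int = 5) -> TraceMatrix:
    """Z-score each neuron using only frames lacking Ca2+ activity.

    Iteratively (at most ``max_iter`` rounds) estimates mean and SD over the
    currently unmasked frames and masks frames exceeding
    ``mean + threshold_sd * SD``, so large transients do not inflate the
    baseline statistics.
    """
    out = np.empty_like(trace.values)
    for j in range(trace.n_neurons):
        x = trace.values[:, j]
        mask = np.zeros(x.size, dtype=bool)
        mean = sd = 0.0
        for _ in range(max_iter):
            keep = ~mask
            if not keep.any():
                raise DegenerateBaselineError(
                    f"all frames masked as active for neuron {trace.neuron_ids[j]}")
            mean = float(x[keep].mean())
            sd = float(x[keep].std(ddof=1)) if keep.sum() > 1 else 0.0
            if sd == 0:
                raise ConstantTraceError(
                    f"constant baseline for neuron {trace.neuron_ids[j]}")
            new_mask = x > mean + threshold_sd * sd
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
        out[:, j] = (x - mean) / sd
    return trace.with_values(out, stage="zscored")


def process_traces(raw: TraceMatrix, baseline: BaselineParams | None = None,
                   t_half_s: float = 0.2) -> dict[str, TraceMatrix]:
    """Run the full chain raw -> f0 -> dff -> standardized -> deconvolved -> zscored."""
    f0 = sliding_baseline(raw, baseline)
    dff = compute_dff(raw, f0)
    std = standardize(dff)
    dec = deconvolve_standin(std, t_half_s=t_half_s)
    z = zscore_activity_masked(dec)
    return {"f0": f0, "dff": dff, "standardized": std, "deconvolved": dec, "zscored": z}
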