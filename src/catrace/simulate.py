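"""Synthetic two-photon recordings of mixed engram / non-engram populations.

The generator emulates the statistical structure the downstream analyses
assume: 10 Hz GCaMP6f recordings (exponential transient decay with a
200 ms half-life), sessions tiled by alternating freezing / non-freezing
bouts, state-modulated Poisson event rates for behaviorally selective
neurons, slow multiplicative baseline drift, and additive Gaussian noise.
It also produces multinomial immunostaining count tables (DAPI cells split
into mCherry-only / cFOS-only / overlap / neither) with a controllable
overlap enrichment over the chance product.

Every draw flows from a single integer seed; identical configurations give
bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (FREEZING, NONFREEZING, BehaviorTrack, InvalidConfigError,
                   TraceMatrix)

SELECTIVITY_CLASSES = (FREEZING, NONFREEZING, "nonselective")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated session.

    Rates are events/s, times in seconds, fluorescence in arbitrary camera
    units.  ``modulation_factor`` multiplies (divides) the event rate of
    freezing-selective (non-freezing-selective) neurons during freezing
    bouts; ``modulation_factor = 1`` is the behavioral null.
    """

    n_neurons: int = 100
    frac_engram: float = 0.3
    frac_freezing_selective: float = 0.0
    duration_s: float = 600.0
    frame_rate_hz: float = 10.0
    kernel_rise_s: float = 0.05
    kernel_t_half_s: float = 0.2
    base_rate_hz: float = 0.05
    modulation_factor: float = 1.0
    baseline_level: float = 100.0
    drift_amplitude: float = 0.1
    noise_sd: float = 1.0
    bout_mean_s: float = 12.0
    target_occupancy: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_engram", "frac_freezing_selective", "target_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if not self.duration_s > 0:
            raise InvalidConfigError("duration_s must be > 0")
        if not self.frame_rate_hz > 0:
            raise InvalidConfigError("frame_rate_hz must be > 0")
        if not self.baseline_level > 0:
            raise InvalidConfigError("baseline_level must be > 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.base_rate_hz < 0:
            raise InvalidConfigError("base_rate_hz must be >= 0")
        if not self.modulation_factor > 0:
            raise InvalidConfigError("modulation_factor must be > 0")
        if not self.kernel_t_half_s > 0:
            raise InvalidConfigError("kernel_t_half_s must be > 0")
        if self.kernel_rise_s < 0:
            raise InvalidConfigError("kernel_rise_s must be >= 0")
        if not self.bout_mean_s > 0:
            raise InvalidConfigError("bout_mean_s must be > 0")
        if self.drift_amplitude < 0:
            raise InvalidConfigError("drift_amplitude must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass(frozen=True)
class GroundTruth:
    """Per-neuron labels and event times the simulator drew from."""

    engram_labels: np.ndarray                 # bool, (n_neurons,)
    selectivity_labels: tuple[str, ...]       # each in SELECTIVITY_CLASSES
    event_times: tuple[np.ndarray, ...]       # ordered seconds per neuron

    def __post_init__(self) -> None:
        n = len(self.engram_labels)
        if len(self.selectivity_labels) != n or len(self.event_times) != n:
            raise InvalidConfigError("ground-truth arrays must share length n_neurons")


@dataclass(frozen=True)
class SimulatedSession:
    traces: TraceMatrix
    behavior: BehaviorTrack
    truth: GroundTruth

    def __post_init__(self) -> None:
        if abs(self.traces.duration_s - self.behavior.duration_s) > 1.0 / self.traces.frame_rate_hz:
            raise InvalidConfigError("traces and behavior must span the same duration")


def simulate_behavior(config: SimConfig, rng: np.random.Generator) -> BehaviorTrack:
    """Draw alternating freezing / non-freezing bouts covering the session.

    Bout lengths are exponential (mean chosen so the expected freezing
    occupancy equals ``target_occupancy`` while the grand bout mean stays at
    ``bout_mean_s``), quantized to whole frames with a 2-frame floor.  The
    track is resampled (up to 100 attempts) until the realized occupancy is
    within 10 percentage points of the target.
    """
    fs = config.frame_rate_hz
    total = config.duration_s
    occ = config.target_occupancy
    if occ == 0.0:
        return BehaviorTrack(((NONFREEZING, 0.0, total),))
    if occ == 1.0:
        return BehaviorTrack(((FREEZING, 0.0, total),))

    mean_f = 2.0 * config.bout_mean_s * occ
    mean_nf = 2.0 * config.bout_mean_s * (1.0 - occ)
    floor = 2.0 / fs
    if mean_f < floor or mean_nf < floor:
        raise InvalidConfigError(
            "target occupancy unreachable: expected bout length below the 2-frame floor")

    for _ in range(100):
        states: list[str] = []
        lengths: list[float] = []
        state = FREEZING if rng.random() < occ else NONFREEZING
        t = 0.0
        while t < total - 1e-9:
            mean = mean_f if state == FREEZING else mean_nf
            # whole-frame bout lengths with a 2-frame floor
            length = max(floor, round(rng.exponential(mean) * fs) / fs)
            length = min(length, total - t)
            states.append(state)
            lengths.append(length)
            t += length
            state = NONFREEZING if state == FREEZING else FREEZING
        track = BehaviorTrack.from_bouts(states, lengths)
        realized = track.occupancy(FREEZING)
        if abs(realized - occ) <= 0.10 or total < 300.0:
            return track
    raise InvalidConfigError(
        f"could not reach occupancy {occ} +/- 0.10 in 100 attempts")


def transient_kernel(t: np.ndarray, rise_s: float, t_half_s: float) -> np.ndarray:
    """Unit-peak transient shape: linear rise, then exponential decay."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    if rise_s > 0:
        rising = (t >= 0) & (t < rise_s)
        out[rising] = t[rising] / rise_s
    decaying = t >= rise_s
    out[decaying] = np.exp2(-(t[decaying] - rise_s) / t_half_s)
    return out


def _draw_event_times(track: BehaviorTrack, base_rate: float, modulation: float,
                      selectivity: str, rng: np.random.Generator) -> np.ndarray:
    """Poisson event times with a piecewise-constant, state-dependent rate."""
    times: list[np.ndarray] = []
    for state, start, end in track.bouts:
        rate = base_rate
        if state == FREEZING:
            if selectivity == FREEZING:
                rate *= modulation
            elif selectivity == NONFREEZING:
                rate /= modulation
        n = rng.poisson(rate * (end - start))
        if n:
            times.append(rng.uniform(start, end, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def simulate_session(config: SimConfig) -> SimulatedSession:
    """Generate one full session: traces, behavior, and ground truth.

    Per neuron, events follow an inhomogeneous Poisson process (rate
    modulated during freezing according to the neuron's selectivity label);
    each event adds a unit-peak kernel; fluorescence is
    ``baseline * (1 + drift) * (1 + sum of kernels) + N(0, noise_sd)`` with
    a slow sinusoidal drift of relative amplitude ``drift_amplitude``.
    """
    rng = np.random.default_rng(config.seed)
    behavior = simulate_behavior(config, rng)
    n_frames = config.n_frames
    fs = config.frame_rate_hz
    frame_t = np.arange(n_frames) / fs

    n = config.n_neurons
    n_engram = int(round(config.frac_engram * n))
    engram = np.zeros(n, dtype=bool)
    engram[rng.choice(n, size=n_engram, replace=False)] = True

    n_sel = int(round(config.frac_freezing_selective * n))
    labels = ["nonselective"] * n
    for i in rng.choice(n, size=n_sel, replace=False):
        labels[i] = FREEZING

    drift_period = config.duration_s          # one slow cycle per session
    phase = rng.uniform(0, 2 * np.pi)
    drift = config.drift_amplitude * np.sin(2 * np.pi * frame_t / drift_period + phase)

    values = np.empty((n_frames, n))
    event_times: list[np.ndarray] = []
    # kernel evaluated out to where it has decayed below 1e-4 of peak
    tail_s = config.kernel_rise_s + config.kernel_t_half_s * np.log2(1e4)
    tail_frames = int(np.ceil(tail_s * fs)) + 1
    for j in range(n):
        times = _draw_event_times(behavior, config.base_rate_hz,
                                  config.modulation_factor, labels[j], rng)
        event_times.append(times)
        activity = np.zeros(n_frames)
        for t0 in times:
            k0 = int(np.ceil(t0 * fs))
            k1 = min(n_frames, k0 + tail_frames)
            if k0 >= n_frames:
                continue
            activity[k0:k1] += transient_kernel(
                frame_t[k0:k1] - t0, config.kernel_rise_s, config.kernel_t_half_s)
        trace = config.baseline_level * (1.0 + drift) * (1.0 + activity)
        if config.noise_sd > 0:
            trace = trace + rng.normal(0.0, config.noise_sd, size=n_frames)
        values[:, j] = trace

    traces = TraceMatrix(values, frame_rate_hz=fs, stage="raw")
    truth = GroundTruth(engram_labels=engram,
                        selectivity_labels=tuple(labels),
                        event_times=tuple(event_times))
    return SimulatedSession(traces=traces, behavior=behavior, truth=truth)


def simulate_count_table(n_slices: int, n_dapi: int, p_mcherry: float,
                         p_cfos: float, overlap_enrichment: float,
                         rng: np.random.Generator, n_mice: int = 1,
                         region: str = "dDG") -> pd.DataFrame:
    """Multinomial immunostaining counts for ``n_slices`` slices.

    Each DAPI nucleus falls into {mCherry only, cFOS only, both, neither}
    with ``P(both) = p_mcherry * p_cfos * overlap_enrichment``; enrichment 1
    is chance-level overlap.  Slices are assigned round-robin to ``n_mice``
    mice.  Columns follow the package's count-table schema.
    """
    if not (0.0 <= p_mcherry <= 1.0 and 0.0 <= p_cfos <= 1.0):
        raise InvalidConfigError("marker probabilities must lie in [0, 1]")
    if overlap_enrichment < 0:
        raise InvalidConfigError("overlap_enrichment must be >= 0")
    p_both = p_mcherry * p_cfos * overlap_enrichment
    if p_both > min(p_mcherry, p_cfos) + 1e-12:
        raise InvalidConfigError(
            "overlap probability exceeds a marginal: reduce overlap_enrichment")
    probs = np.array([p_mcherry - p_both, p_cfos - p_both, p_both,
                      1.0 - p_mcherry - p_cfos + p_both])
    if np.any(probs < -1e-12):
        raise InvalidConfigError("inconsistent marker probabilities")
    probs = np.clip(probs, 0.0, 1.0)
    probs = probs / probs.sum()

    draws = rng.multinomial(n_dapi, probs, size=n_slices)
    rows = []
    for s, (m_only, c_only, both, _) in enumerate(draws):
        rows.append({
            "mouse_id": f"m{s % n_mice}",
            "slice_id": f"s{s}",
            "region": region,
            "n_dapi": n_dapi,
            "n_marker1": int(m_only + both),
            "n_marker2": int(c_only + both),
            "n_overlap": int(both),
        })
    return pd.DataFrame(rows)
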