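"""Shared containers and errors for the calcium-trace pipeline.

Conventions used throughout the package: time is in seconds, frames are
0-based, and intervals are half-open ``[start, end)``.  Frame ``i`` of a
recording at ``frame_rate_hz`` covers the time slice
``[i / frame_rate_hz, (i + 1) / frame_rate_hz)``; a frame belongs to the
behavioral bout that contains its start time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

FREEZING = "freezing"
NONFREEZING = "nonfreezing"
STATES = (FREEZING, NONFREEZING)

STAGES = ("raw", "dff", "standardized", "deconvolved", "zscored")


class CatraceError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CatraceError, ValueError):
    """A configuration value violates its invariants."""


class NonpositiveBaselineError(CatraceError, ValueError):
    """F0 is not strictly positive; raw units are invalid for dF/F."""


class ConstantTraceError(CatraceError, ValueError):
    """A per-neuron trace has zero variance where variance is required."""


class DegenerateBaselineError(CatraceError, ValueError):
    """Activity masking removed every frame; no baseline left to estimate."""


class StageError(CatraceError, ValueError):
    """A trace matrix is at the wrong processing stage for an operation."""


class FormatError(CatraceError, ValueError):
    """An input file is malformed."""


@dataclass(frozen=True)
class TraceMatrix:
    """Fluorescence values, frames x neurons, at a fixed frame rate.

    ``stage`` tracks where the matrix sits in the processing chain:
    ``raw`` (camera units) -> ``dff`` -> ``standardized`` (SD units)
    -> ``deconvolved`` -> ``zscored``.
    """

    values: np.ndarray
    frame_rate_hz: float
    stage: str = "raw"
    neuron_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2:
            raise FormatError("trace matrix must be 2-D (frames x neurons)")
        if values.shape[0] < 2:
            raise FormatError("trace matrix needs at least 2 frames")
        if not np.all(np.isfinite(values)):
            raise FormatError("trace matrix contains non-finite values")
        if not self.frame_rate_hz > 0:
            raise InvalidConfigError("frame_rate_hz must be > 0")
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        ids = self.neuron_ids or tuple(f"n{j}" for j in range(values.shape[1]))
        if len(ids) != values.shape[1]:
            raise FormatError("neuron_ids length must match neuron count")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "neuron_ids", tuple(ids))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def with_values(self, values: np.ndarray, stage: str) -> "TraceMatrix":
        return replace(self, values=values, stage=stage)


@dataclass(frozen=True)
class BehaviorTrack:
    """Ordered freezing / non-freezing bouts tiling ``[0, duration)``.

    Bouts are half-open ``(state, start_s, end_s)`` triples with no gaps or
    overlaps; adjacent bouts in the same state are merged on construction.
    """

    bouts: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bouts:
            raise FormatError("behavior track has no bouts")
        merged: list[tuple[str, float, float]] = []
        t = 0.0
        for state, start, end in self.bouts:
            if state not in STATES:
                raise FormatError(f"unknown behavioral state {state!r}")
            if not (end > start >= 0):
                raise FormatError(f"bad bout interval [{start}, {end})")
            if abs(start - t) > 1e-9:
                raise FormatError(f"bout starting at {start} leaves a gap/overlap at {t}")
            if merged and merged[-1][0] == state:
                merged[-1] = (state, merged[-1][1], end)
            else:
                merged.append((state, start, end))
            t = end
        object.__setattr__(self, "bouts", tuple(merged))

    @property
    def duration_s(self) -> float:
        return self.bouts[-1][2]

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    def state_time(self, state: str) -> float:
        """Total seconds spent in ``state``."""
        return sum(e - s for st, s, e in self.bouts if st == state)

    def occupancy(self, state: str = FREEZING) -> float:
        return self.state_time(state) / self.duration_s

    def frame_counts(self, frame_rate_hz: float, n_frames: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Per-bout frame counts at a frame rate.

        Returns ``(is_freezing, counts)`` aligned with ``bouts``; frame ``i``
        is assigned to the bout containing time ``i / frame_rate_hz``.  The
        counts sum to ``n_frames`` (default: frames fitting the duration).
        """
        if n_frames is None:
            n_frames = int(round(self.duration_s * frame_rate_hz))
        edges = np.array([s for _, s, _ in self.bouts] + [self.bouts[-1][2]])
        # first frame index at or after each bout edge
        idx = np.ceil(edges * frame_rate_hz - 1e-9).astype(int)
        idx = np.clip(idx, 0, n_frames)
        idx[-1] = n_frames
        counts = np.diff(idx)
        is_freezing = np.array([st == FREEZING for st, _, _ in self.bouts])
        return is_freezing, counts

    def frame_mask(self, frame_rate_hz: float, n_frames: int | None = None) -> np.ndarray:
        """Boolean per-frame mask, True where the animal is freezing."""
        is_freezing, counts = self.frame_counts(frame_rate_hz, n_frames)
        return np.repeat(is_freezing, counts)

    @staticmethod
    def from_bouts(states: Sequence[str], lengths_s: Sequence[float]) -> "BehaviorTrack":
        """Build a track from bout states and lengths, concatenated from 0."""
        starts = np.concatenate([[0.0], np.cumsum(lengths_s)[:-1]])
        ends = np.cumsum(lengths_s)
        return BehaviorTrack(tuple(zip(states, starts, ends)))


@dataclass(frozen=True)
class TransientEvent:
    """One detected Ca2+ transient.

    Frames are 0-based; ``onset_frame`` inclusive, ``offset_frame``
    exclusive; ``amplitude_sd`` is the peak height of the standardized
    trace within the event envelope.
    """

    neuron_id: str
    onset_frame: int
    offset_frame: int
    peak_frame: int
    amplitude_sd: float
    duration_s: float

    def __post_init__(self) -> None:
        if not (self.onset_frame <= self.peak_frame < self.offset_frame):
            raise CatraceError(
                f"peak frame {self.peak_frame} outside envelope "
                f"[{self.onset_frame}, {self.offset_frame})")
        if self.duration_s <= 0:
            raise CatraceError("event duration must be positive")


@dataclass
class NeuronRecord:
    """Per-neuron engram label and derived classifications."""

    neuron_id: str
    engram: bool
    auc_per_sec: float = float("nan")
    activity_class: str | None = None          # "active" | "inactive"
    selectivity_class: str | None = None       # "freezing" | "nonfreezing" | "nonselective"
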