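"""In-memory containers for electrophysiology and imaging records.

All time axes are in ms, currents in pA, voltages in mV, capacitances in pF,
lengths in um — the single unit convention used throughout files and APIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["LightEvent", "CurrentTrace", "CapacitanceTrace", "LineProfileStack"]

UV = "UV"
BLUE = "BLUE"


class InvalidProtocolError(ValueError):
    """Light-event protocol violates ordering/overlap constraints."""


@dataclass(frozen=True)
class LightEvent:
    """A single illumination pulse.

    kind "UV" drives trans→cis (thinner membrane, capacitance increase);
    kind "BLUE" drives cis→trans (thicker membrane, capacitance decrease).
    """

    t_on_ms: float
    duration_ms: float
    kind: str  # "UV" | "BLUE"

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise InvalidProtocolError("pulse duration must be positive")
        if self.kind not in (UV, BLUE):
            raise InvalidProtocolError(f"unknown light kind {self.kind!r}")

    @property
    def t_off_ms(self) -> float:
        return self.t_on_ms + self.duration_ms


def validate_events(events: Sequence[LightEvent]) -> None:
    """Events must be time-ordered and non-overlapping."""
    for prev, nxt in zip(events, events[1:]):
        if nxt.t_on_ms < prev.t_off_ms:
            raise InvalidProtocolError(
                f"events overlap: pulse at {nxt.t_on_ms} ms starts before the "
                f"pulse at {prev.t_on_ms} ms ends ({prev.t_off_ms} ms)"
            )


def _require_uniform(time_ms: np.ndarray, jitter_tol: float = 0.01) -> float:
    """Return the sampling interval; reject non-uniform time bases."""
    dt = np.diff(time_ms)
    if len(dt) == 0:
        raise ValueError("trace needs at least two samples")
    dt0 = float(np.median(dt))
    if dt0 <= 0 or np.any(np.abs(dt - dt0) > jitter_tol * dt0):
        bad = int(np.argmax(np.abs(dt - dt0)))
        raise ValueError(
            f"non-uniform time base: interval at row {bad} deviates from the "
            f"median {dt0:.6g} ms by more than {jitter_tol:.0%}"
        )
    return dt0


@dataclass
class CurrentTrace:
    """Uniformly sampled voltage-clamp current record with light events.

    ``n_open`` optionally carries the simulator's hidden open-channel count
    per sample; analysis code never reads it, oracles in tests do.
    """

    time_ms: np.ndarray
    i_pA: np.ndarray
    v_mV: np.ndarray  # piecewise-constant command voltage per sample
    events: list[LightEvent] = field(default_factory=list)
    sampling_rate_khz: float = 25.0
    filter_cutoff_khz: float = 10.0
    n_open: np.ndarray | None = None
    # simulator bookkeeping: effective kinetic-regime toggle time per
    # (channel, event); analysis code never reads it, test oracles do
    toggle_times_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.i_pA = np.asarray(self.i_pA, dtype=float)
        self.v_mV = np.broadcast_to(
            np.asarray(self.v_mV, dtype=float), self.time_ms.shape
        ).copy()
        if not np.all(np.isfinite(self.i_pA)):
            raise ValueError("current contains non-finite samples")
        _require_uniform(self.time_ms)
        validate_events(self.events)

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class CapacitanceTrace:
    """Uniformly sampled lock-in membrane-capacitance record."""

    time_ms: np.ndarray
    cm_pF: np.ndarray
    events: list[LightEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.cm_pF = np.asarray(self.cm_pF, dtype=float)
        if not np.all(np.isfinite(self.cm_pF)):
            raise ValueError("capacitance contains non-finite samples")
        _require_uniform(self.time_ms)

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class LineProfileStack:
    """Per-frame averaged equatorial intensity profiles of the torus region.

    ``frames`` is (n_frames, n_pixels); row i is the mean of the
    ``n_lines_averaged`` raw camera lines of frame i.
    """

    frames: np.ndarray
    pixel_um: float
    frame_ms: float
    n_lines_averaged: int = 11

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frame_ms <= 0:
            raise ValueError("frame interval must be positive")
        if self.n_lines_averaged < 1:
            raise ValueError("n_lines_averaged must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.frames.shape[1]
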