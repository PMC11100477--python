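"""Shared domain containers: pulse annotations and F0 contours."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PulseAnnotation:
    """One annotated pulse within a long-call recording.

    Times are seconds from recording start; intervals are half-open
    ``[begin_time, end_time)``. ``tonal``/``noisy``/``f0_valid`` are the
    quality flags used to screen pulses before feature measurement.
    ``observer_labels`` maps observer name to the pulse-type label that
    observer assigned.
    """

    recording_id: str
    begin_time: float
    end_time: float
    low_freq: float = 50.0
    high_freq: float = 1000.0
    tonal: bool = True
    noisy: bool = False
    f0_valid: bool = True
    pulse_id: str | None = None
    observer_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.end_time > self.begin_time:
            raise ValueError(
                f"end_time ({self.end_time}) must exceed begin_time ({self.begin_time})"
            )
        if not self.low_freq < self.high_freq:
            raise ValueError(
                f"low_freq ({self.low_freq}) must be below high_freq ({self.high_freq})"
            )

    @property
    def duration(self) -> float:
        return self.end_time - self.begin_time

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.begin_time + self.end_time)


@dataclass
class F0Contour:
    """Per-frame fundamental-frequency track of one pulse.

    ``f0_hz`` holds NaN at unvoiced frames; ``voiced`` is the boolean mask.
    ``band`` is the (low, high) search band in Hz and ``amp_threshold`` the
    relative amplitude gate used (or intended) for voicing decisions.
    """

    frame_times: np.ndarray
    f0_hz: np.ndarray
    band: tuple[float, float] = (50.0, 1500.0)
    amp_threshold: float = 0.85

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.f0_hz = np.asarray(self.f0_hz, dtype=float)
        if self.frame_times.shape != self.f0_hz.shape:
            raise ValueError("frame_times and f0_hz must have identical shape")

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0_hz)

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())

    @property
    def f0_min(self) -> float:
        v = self.f0_hz[self.voiced]
        return float(v.min()) if v.size else float("nan")

    @property
    def f0_max(self) -> float:
        v = self.f0_hz[self.voiced]
        return float(v.max()) if v.size else float("nan")
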