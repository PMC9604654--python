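"""Biphasic pulse-train protocol and its gating schedule.

Default protocol: 5 trains of 8 biphasic pulses; pulse width and pulse
interval both 100 us; 198.4 ms between trains — total duration exactly 1 s,
total energized (on) time 4 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["PulseProtocol", "GatingSchedule", "gating_schedule",
           "sample_waveform"]


@dataclass(frozen=True)
class PulseProtocol:
    amplitude: float = 1000.0        # V
    pulse_width: float = 100e-6      # s
    pulse_interval: float = 100e-6   # s
    pulses_per_train: int = 8
    n_trains: int = 5
    train_interval: float = 198.4e-3  # s
    polarity: str = "BIPHASIC"       # "BIPHASIC" | "MONOPHASIC"

    def __post_init__(self):
        for name in ("amplitude", "pulse_width", "pulse_interval",
                     "train_interval"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.pulses_per_train < 1 or self.n_trains < 1:
            raise DomainError("pulse/train counts must be >= 1")
        if self.polarity not in ("BIPHASIC", "MONOPHASIC"):
            raise DomainError(f"unknown polarity {self.polarity!r}")

    @property
    def train_active_span(self) -> float:
        """Duration of one train's pulses + intervals."""
        return self.pulses_per_train * (self.pulse_width + self.pulse_interval)

    @property
    def total_duration(self) -> float:
        return self.n_trains * (self.train_active_span + self.train_interval)

    @property
    def total_on_time(self) -> float:
        return self.n_trains * self.pulses_per_train * self.pulse_width

    @property
    def duty_cycle(self) -> float:
        return self.total_on_time / self.total_duration


@dataclass(frozen=True)
class GatingSchedule:
    """Sorted, disjoint on-intervals of the energized source."""

    intervals: tuple[tuple[float, float], ...]
    total_duration: float
    total_on_time: float

    def on_fraction(self, t0: float, t1: float) -> float:
        """Fraction of [t0, t1] overlapping on-intervals (exact)."""
        if t1 <= t0:
            raise DomainError("empty time window")
        overlap = 0.0
        for a, b in self.intervals:
            overlap += max(0.0, min(b, t1) - max(a, t0))
        return overlap / (t1 - t0)


def gating_schedule(protocol: PulseProtocol) -> GatingSchedule:
    """On-intervals of every pulse: train = pulses+intervals, then the train
    interval; the printed parameters total exactly 1 s."""
    intervals = []
    period = protocol.pulse_width + protocol.pulse_interval
    for train in range(protocol.n_trains):
        t0 = train * (protocol.train_active_span + protocol.train_interval)
        for p in range(protocol.pulses_per_train):
            start = t0 + p * period
            intervals.append((start, start + protocol.pulse_width))
    return GatingSchedule(intervals=tuple(intervals),
                          total_duration=protocol.total_duration,
                          total_on_time=protocol.total_on_time)


def sample_waveform(protocol: PulseProtocol, t) -> float | np.ndarray:
    """Voltage P(t): +/- amplitude alternating per pulse during on-intervals
    (biphasic), +amplitude (monophasic), 0 during intervals."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0) or np.any(tt > protocol.total_duration):
        raise DomainError("t outside [0, total_duration]")
    period = protocol.pulse_width + protocol.pulse_interval
    block = protocol.train_active_span + protocol.train_interval
    in_train = np.mod(tt, block)
    pulse_idx = np.floor_divide(in_train, period).astype(int)
    in_pulse = (np.mod(in_train, period) < protocol.pulse_width) \
        & (pulse_idx < protocol.pulses_per_train)
    if protocol.polarity == "BIPHASIC":
        sign = np.where(pulse_idx % 2 == 0, 1.0, -1.0)
    else:
        sign = np.ones_like(tt)
    out = np.where(in_pulse, sign * protocol.amplitude, 0.0)
    return out if out.ndim else float(out)


def waveform_samples(protocol: PulseProtocol, dt: float = 5e-6) -> np.ndarray:
    """(T, 2) array of (t, V) samples over the full protocol, for export."""
    t = np.arange(0.0, protocol.total_duration, dt)
    return np.column_stack([t, sample_waveform(protocol, t)])
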