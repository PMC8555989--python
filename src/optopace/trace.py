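"""Core time-series containers: uniformly sampled traces and pulse trains."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError


@dataclass
class TimeTrace:
    """A uniformly sampled scalar signal (ECG, TTL, respiration, fluorescence).

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz); must be positive.
    samples : ndarray
        Signal values; non-empty 1-D array.
    start_time : float, optional
        Absolute time of the first sample in seconds.
    """

    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D array")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds."""
        return (self.n - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Nearest sample index to absolute time ``t``, clipped to range."""
        i = int(round((t - self.start_time) * self.sampling_rate))
        return min(max(i, 0), self.n - 1)


@dataclass
class PulseTrain:
    """Laser stimulation events as alternating rising/falling edge times (s)."""

    rising_edges: np.ndarray = field(default_factory=lambda: np.empty(0))
    falling_edges: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.rising_edges = np.asarray(self.rising_edges, dtype=float)
        self.falling_edges = np.asarray(self.falling_edges, dtype=float)
        if self.rising_edges.size != self.falling_edges.size:
            raise ValidationError("rising and falling edge counts differ")
        if self.rising_edges.size:
            if np.any(np.diff(self.rising_edges) <= 0):
                raise ValidationError("rising edges must be strictly increasing")
            if np.any(self.falling_edges - self.rising_edges <= 0):
                raise ValidationError("each falling edge must follow its rising edge")
            # edges must alternate: falling[i] < rising[i+1]
            if np.any(self.rising_edges[1:] - self.falling_edges[:-1] <= 0):
                raise ValidationError("pulses overlap: edges do not alternate")

    @property
    def n_pulses(self) -> int:
        return int(self.rising_edges.size)

    @property
    def pulse_length_ms(self) -> float:
        """Median pulse duration in milliseconds (NaN when empty)."""
        if not self.n_pulses:
            return float("nan")
        return float(np.median(self.falling_edges - self.rising_edges) * 1000.0)

    def shifted(self, dt: float) -> "PulseTrain":
        return PulseTrain(self.rising_edges + dt, self.falling_edges + dt)
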