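"""Core signal containers: uniformly sampled time series, epochs, NN series.

All channels in a recording share one of three kinds: ``ppg`` (arbitrary
units), ``eda`` (microsiemens), ``skt`` (degrees Celsius).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

CHANNELS = ("ppg", "eda", "skt")

#: Canonical session order: baseline, mild, moderate, severe stress, recovery.
SESSIONS = ("BA-S", "MIS-S", "MOS-S", "SES-S", "RE-S")


@dataclass
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Signal values; must be finite and non-empty.
    fs : float
        Sampling rate in Hz, > 0.
    channel : str
        One of ``ppg``, ``eda``, ``skt``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if self.channel not in CHANNELS:
            raise InvalidArgumentError(
                f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def slice_time(self, start: float, stop: float) -> "TimeSeries":
        """Return the half-open time slice [start, stop) as a new TimeSeries."""
        i0 = int(round((start - self.t0) * self.fs))
        i1 = int(round((stop - self.t0) * self.fs))
        i0 = max(i0, 0)
        i1 = min(i1, self.n)
        if i1 <= i0:
            raise InvalidArgumentError("empty time slice")
        return replace(self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs)


@dataclass
class NNSeries:
    """Detected pulse peak times (s) and normal-to-normal intervals (ms).

    ``nn[i] = (peak_times[i+1] - peak_times[i]) * 1000``.
    """

    peak_times: np.ndarray
    nn: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size < 2:
            raise InvalidArgumentError("NNSeries needs at least 2 peaks")
        d = np.diff(self.peak_times)
        if np.any(d <= 0):
            raise InvalidArgumentError("peak times must be strictly increasing")
        self.nn = d * 1000.0

    def __len__(self) -> int:
        return self.nn.size


@dataclass
class EpochSet:
    """Consecutive non-overlapping fixed-duration epochs of one session."""

    epochs: list
    epoch_duration: float
    discard_lead: float
    subject_id: str = ""
    session_label: str = ""

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)
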