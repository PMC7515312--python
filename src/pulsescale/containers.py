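"""Core domain containers for heart-beat series analysis.

The central object is :class:`RRSeries` — a sequence of inter-beat (RR)
intervals in milliseconds, each timestamped by the beat that *ends* it.
Raw ECG is carried by :class:`ECGSignal`, detected R peaks by
:class:`RPeakTrain`, and scaled (coarse-grained / moving-average /
volatility) series by :class:`ScaledSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ECGSignal",
    "RPeakTrain",
    "RRSeries",
    "DRRSeries",
    "WindowSpec",
    "ScaledSeries",
    "PulsescaleError",
    "InvalidBandError",
    "DataError",
    "InsufficientDataError",
]


class PulsescaleError(Exception):
    """Base class for all pulsescale errors."""


class InvalidBandError(PulsescaleError, ValueError):
    """Filter band is incompatible with the sampling rate."""


class DataError(PulsescaleError, ValueError):
    """Input data violates a basic contract (non-finite, negative, ...)."""


class InsufficientDataError(PulsescaleError, ValueError):
    """Series is too short for the requested operation."""


@dataclass(frozen=True)
class ECGSignal:
    """Uniformly sampled single-lead ECG voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples, arbitrary units; must be finite.
    fs : float
        Sampling rate in Hz (> 0). Default 250.
    start_time : float
        Offset of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float = 250.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(samples)):
            raise DataError("ECG samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.start_time + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class RPeakTrain:
    """Strictly increasing R-peak times in seconds."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.peak_times, dtype=float)
        object.__setattr__(self, "peak_times", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise DataError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass(frozen=True)
class RRSeries:
    """Inter-beat interval series.

    ``intervals`` are in milliseconds; ``beat_times`` (seconds) timestamp
    the beat that ends each interval, so ``len(beat_times) ==
    len(intervals)``. ``clean`` is set by the artifact filter; a clean
    series has every interval within the physiological range
    [280, 1500] ms and no >20% jump between consecutive kept beats.
    """

    intervals: np.ndarray
    beat_times: np.ndarray | None = None
    clean: bool = False

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if np.any(~np.isfinite(iv)):
            raise DataError("RR intervals contain non-finite values")
        if np.any(iv <= 0):
            raise DataError("RR intervals must be positive")
        if self.beat_times is None:
            bt = np.cumsum(iv) / 1000.0
        else:
            bt = np.asarray(self.beat_times, dtype=float)
            if bt.shape != iv.shape:
                raise DataError("beat_times must match intervals in length")
            if bt.size and np.any(np.diff(bt) <= 0):
                raise DataError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times", bt)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration(self) -> float:
        """Span in seconds from the start of the first interval."""
        if len(self.intervals) == 0:
            return 0.0
        start = self.beat_times[0] - self.intervals[0] / 1000.0
        return float(self.beat_times[-1] - start)


@dataclass(frozen=True)
class DRRSeries:
    """Absolute successive differences of an RR series, |RR_{i+1} - RR_i| (ms)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if np.any(vals < 0):
            raise DataError("dRR values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis window: ``length`` seconds advanced by ``step`` seconds.

    Defaults give the standard 5-min HRV window with 4-min overlap.
    """

    length: float = 300.0
    step: float = 60.0
    min_beats: int = 60

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.length:
            raise DataError(
                f"need 0 < step <= length, got step={self.step}, length={self.length}"
            )


@dataclass(frozen=True)
class ScaledSeries:
    """A series transformed by one scaling algorithm at one scale.

    ``method`` is one of ``cg`` (coarse graining), ``mavg`` (moving
    average), ``comp_cg`` (one member of the composite coarse graining),
    ``mom`` (block standard deviation / volatility) or ``mavg_mom``
    (sliding volatility). ``grain_index`` identifies the composite member
    (1-based) and is None for the other methods.
    """

    values: np.ndarray
    scale: int
    method: str
    grain_index: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.scale < 1:
            raise DataError(f"scale must be >= 1, got {self.scale}")

    def __len__(self) -> int:
        return len(self.values)
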