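"""Shared signal primitives.

Container types for uniformly sampled traces, epoch (interval) sets and
analytic phase/amplitude series, together with the basic transforms every
analysis stage relies on: z-scoring, zero-phase Butterworth band-pass
filtering, Hilbert phase/envelope extraction and epoch masking.

Phase convention
----------------
Instantaneous phase is the angle of the analytic signal, so for a cosine-like
oscillation phase 0 falls on the waveform *peak* and -pi/+pi on the troughs.
All downstream modules (phase-phase coupling, phase-amplitude coupling,
spike-phase histograms) inherit this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps

__all__ = [
    "Signal",
    "EpochSet",
    "PhaseSeries",
    "AmplitudeSeries",
    "DegenerateSignalError",
    "InsufficientDataError",
    "PHASE_BIN_EDGES",
    "N_PHASE_BINS",
    "zscore",
    "bandpass",
    "analytic_phase",
    "analytic_amplitude",
    "mask_epochs",
    "wrap_phase",
]

#: Phase histograms everywhere use 18 bins of 20 degrees spanning [-pi, pi).
N_PHASE_BINS = 18
PHASE_BIN_EDGES = np.linspace(-np.pi, np.pi, N_PHASE_BINS + 1)
PHASE_BIN_CENTERS = 0.5 * (PHASE_BIN_EDGES[:-1] + PHASE_BIN_EDGES[1:])


class DegenerateSignalError(ValueError):
    """Raised when an input carries no usable structure (constant, empty...)."""


class InsufficientDataError(ValueError):
    """Raised when the data do not cover the minimum analysis window."""


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : ndarray
        The sample values.
    fs : float
        Sampling rate in Hz (> 0).
    label : str
        Free-text channel label (e.g. ``"lfp"``, ``"respiration"``).
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "Signal":
        return replace(self, samples=samples, label=self.label if label is None else label)


@dataclass(frozen=True)
class EpochSet:
    """Ordered, non-overlapping half-open intervals ``[start, end)`` in seconds."""

    intervals: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        iv = tuple((float(a), float(b)) for a, b in self.intervals)
        for a, b in iv:
            if not a < b:
                raise ValueError(f"interval [{a}, {b}) has non-positive length")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("intervals overlap or are unsorted")
        object.__setattr__(self, "intervals", iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_duration(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def clip(self, t_lo: float, t_hi: float) -> "EpochSet":
        """Intersect every interval with ``[t_lo, t_hi)``."""
        out = []
        for a, b in self.intervals:
            a2, b2 = max(a, t_lo), min(b, t_hi)
            if a2 < b2:
                out.append((a2, b2))
        return EpochSet(tuple(out))

    def intersect(self, other: "EpochSet") -> "EpochSet":
        out = []
        for a, b in self.intervals:
            for c, d in other.intervals:
                lo, hi = max(a, c), min(b, d)
                if lo < hi:
                    out.append((lo, hi))
        return EpochSet(tuple(sorted(out)))

    def filter_min_length(self, min_len_s: float) -> "EpochSet":
        """Drop intervals shorter than ``min_len_s`` (coupling analyses use
        a floor of two slow-rhythm cycles)."""
        return EpochSet(tuple((a, b) for a, b in self.intervals if b - a >= min_len_s))

    @staticmethod
    def merged(intervals, max_gap_s: float = 0.0) -> "EpochSet":
        """Build an EpochSet from possibly touching intervals, merging any
        pair separated by less than ``max_gap_s``."""
        ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
        out: list[list[float]] = []
        for a, b in ivs:
            if out and a - out[-1][1] < max_gap_s:
                out[-1][1] = max(out[-1][1], b)
            else:
                out.append([a, b])
        return EpochSet(tuple((a, b) for a, b in out))


@dataclass(frozen=True)
class PhaseSeries:
    """Per-sample instantaneous phase in [-pi, pi) of a band-limited signal."""

    phase: np.ndarray
    fs: float
    band_hz: tuple[float, float] | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", np.asarray(self.phase, dtype=float))

    @property
    def n(self) -> int:
        return self.phase.size

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class AmplitudeSeries:
    """Per-sample non-negative amplitude envelope of a band-limited signal."""

    envelope: np.ndarray
    fs: float
    band_hz: tuple[float, float] | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        env = np.asarray(self.envelope, dtype=float)
        object.__setattr__(self, "envelope", env)
        if env.size and env.min() < 0:
            raise ValueError("envelope must be non-negative")

    @property
    def n(self) -> int:
        return self.envelope.size


def zscore(signal: Signal) -> Signal:
    """Standardize a trace: subtract the mean and divide by the SD.

    Raises
    ------
    DegenerateSignalError
        If the signal is constant (SD = 0) or shorter than two samples.
    """
    x = signal.samples
    if x.size < 2:
        raise DegenerateSignalError("need at least 2 samples to z-score")
    sd = x.std()
    if sd == 0:
        raise DegenerateSignalError("constant signal cannot be z-scored")
    return signal.with_samples((x - x.mean()) / sd)


def bandpass(signal: Signal, low_hz: float, high_hz: float, order: int = 2) -> Signal:
    """Zero-phase Butterworth band-pass (``filtfilt``; default 2nd order).

    Forward-reverse application doubles the effective order and cancels the
    phase response, so features of the filtered trace stay aligned with the
    raw trace.
    """
    nyq = signal.fs / 2
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=signal.fs, output="sos")
    y = sps.sosfiltfilt(sos, signal.samples)
    return Signal(y, signal.fs, label=f"{signal.label}[{low_hz}-{high_hz}Hz]", t0=signal.t0)


def _analytic(signal: Signal) -> np.ndarray:
    x = signal.samples
    if x.size == 0 or not np.any(x):
        raise DegenerateSignalError("all-zero signal has no analytic phase/amplitude")
    n = x.size
    # pad to a fast FFT length: hilbert on an awkward prime-ish n is slow
    nfft = spfft.next_fast_len(n)
    return sps.hilbert(x, N=nfft)[:n]


def analytic_phase(signal: Signal, band_hz: tuple[float, float] | None = None) -> PhaseSeries:
    """Instantaneous phase from the Hilbert analytic signal.

    For ``cos(2*pi*f*t)`` the phase is 0 at waveform peaks and +/-pi at the
    troughs. Intended for band-limited input (the output of :func:`bandpass`).
    """
    return PhaseSeries(np.angle(_analytic(signal)), signal.fs, band_hz, signal.t0)


def analytic_amplitude(signal: Signal, band_hz: tuple[float, float] | None = None) -> AmplitudeSeries:
    """Instantaneous amplitude envelope from the Hilbert analytic signal."""
    return AmplitudeSeries(np.abs(_analytic(signal)), signal.fs, band_hz, signal.t0)


def _series_array(series) -> tuple[np.ndarray, float, float]:
    if isinstance(series, Signal):
        return series.samples, series.fs, series.t0
    if isinstance(series, PhaseSeries):
        return series.phase, series.fs, series.t0
    if isinstance(series, AmplitudeSeries):
        return series.envelope, series.fs, series.t0
    raise TypeError(f"unsupported series type {type(series).__name__}")


def epoch_sample_slices(series, epochs: EpochSet) -> list[slice]:
    """Sample-index slices corresponding to each epoch interval."""
    arr, fs, t0 = _series_array(series)
    n = arr.size
    out = []
    for a, b in epochs:
        i = int(round((a - t0) * fs))
        j = int(round((b - t0) * fs))
        if i < 0 or j > n:
            raise ValueError(f"epoch [{a}, {b}) s exceeds the recording span")
        out.append(slice(i, j))
    return out

def mask_epochs(series, epochs: EpochSet) -> list[np.ndarray]:
    """Cut a (filtered/transformed) series into per-epoch contiguous segments.

    Transforms are always applied to the full trace first and masked after,
    so short epochs carry no per-segment filter edge artifacts.
    """
    arr, _, _ = _series_array(series)
    return [arr[sl] for sl in epoch_sample_slices(series, epochs)]


def concat_epochs(series, epochs: EpochSet) -> np.ndarray:
    """All samples falling inside the epochs, concatenated in time order."""
    segs = mask_epochs(series, epochs)
    return np.concatenate(segs) if segs else np.empty(0)


def edge_trimmed_epochs(epochs: EpochSet, duration_s: float, margin_s: float = 1.0) -> EpochSet:
    """Clip epochs away from the first/last ``margin_s`` of the recording,
    suppressing filtfilt edge transients."""
    return epochs.clip(margin_s, duration_s - margin_s)
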