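"""Power spectra and LFP-respiration coherence.

PSDs are multitaper estimates (DPSS tapers) computed on disjoint 5 s chunks
cut from the analysis epochs and averaged; the taper set corresponds to a
spectral bandwidth of 1 Hz on those chunks (time-half-bandwidth NW = 2.5,
2*NW - 1 = 4 tapers). Spectra are optionally normalized by frequency to
compensate the 1/f decay of LFP power before band peaks are compared
across bands.

Coherence is Welch magnitude-squared coherence with windows of 0.5 * fs
samples, zero-padded to 10 * fs points, pooled across epoch segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import signal as sps
from scipy.signal import windows

from .core import EpochSet, InsufficientDataError, Signal, mask_epochs

__all__ = [
    "Spectrum",
    "CoherenceSpectrum",
    "BandPeak",
    "multitaper_psd",
    "normalize_1f",
    "band_peak",
    "coherence",
    "BANDS",
]

#: Canonical frequency bands (Hz).
BANDS = {
    "prr": (1.0, 5.0),
    "theta": (6.0, 12.0),
    "gamma": (30.0, 100.0),
    "high_gamma": (80.0, 100.0),
}


@dataclass(frozen=True)
class Spectrum:
    """A one-sided power spectral density."""

    freqs_hz: np.ndarray
    power: np.ndarray
    normalized: bool = False
    n_chunks: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if p.min() < 0:
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class CoherenceSpectrum:
    freqs_hz: np.ndarray
    coherence: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coherence, dtype=float)
        if c.size and (c.min() < 0 or c.max() > 1 + 1e-9):
            raise ValueError("coherence values must lie in [0, 1]")
        object.__setattr__(self, "freqs_hz", np.asarray(self.freqs_hz, dtype=float))
        object.__setattr__(self, "coherence", np.clip(c, 0.0, 1.0))


class BandPeak(NamedTuple):
    peak_freq_hz: float
    peak_power: float
    band_power: float


def _dpss_params(chunk_s: float, bandwidth_hz: float) -> tuple[float, int]:
    """Map a requested spectral bandwidth to DPSS time-half-bandwidth and
    taper count: NW = T * bandwidth / 2, K = floor(2 NW) - 1."""
    nw = chunk_s * bandwidth_hz / 2.0
    k = max(int(2 * nw) - 1, 1)
    return nw, k


def multitaper_psd(
    signal: Signal,
    epochs: EpochSet | None = None,
    chunk_s: float = 5.0,
    bandwidth_hz: float = 1.0,
) -> Spectrum:
    """Multitaper PSD averaged over disjoint ``chunk_s`` chunks.

    Chunks are cut independently inside each epoch (never spanning an
    epoch boundary); incomplete trailing chunks are dropped.
    """
    if epochs is None:
        epochs = EpochSet(((signal.t0, signal.t0 + signal.duration),))
    if len(epochs) == 0:
        raise InsufficientDataError("no epochs supplied")
    n_chunk = int(round(chunk_s * signal.fs))
    chunks = []
    for seg in mask_epochs(signal, epochs):
        for k in range(seg.size // n_chunk):
            chunks.append(seg[k * n_chunk:(k + 1) * n_chunk])
    if not chunks:
        raise InsufficientDataError(
            f"no epoch contains a complete {chunk_s} s chunk"
        )
    x = np.asarray(chunks)  # (n_chunks, n_chunk)
    nw, n_tapers = _dpss_params(chunk_s, bandwidth_hz)
    tapers = windows.dpss(n_chunk, nw, Kmax=n_tapers)  # (K, n), unit energy
    # (n_chunks, K, n) tapered segments -> one-sided density in V^2/Hz
    tapered = x[:, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    psd = (np.abs(spec) ** 2) / signal.fs
    psd[..., 1:] *= 2.0
    if n_chunk % 2 == 0:
        psd[..., -1] /= 2.0
    power = psd.mean(axis=(0, 1))
    freqs = np.fft.rfftfreq(n_chunk, d=1 / signal.fs)
    return Spectrum(freqs, power, normalized=False, n_chunks=len(chunks))


def normalize_1f(spectrum: Spectrum) -> Spectrum:
    """Multiply power by frequency to flatten the 1/f background."""
    if spectrum.normalized:
        raise ValueError("spectrum is already frequency-normalized")
    return replace(spectrum, power=spectrum.power * spectrum.freqs_hz, normalized=True)


def band_peak(spectrum: Spectrum, band_hz: tuple[float, float]) -> BandPeak:
    """Peak frequency and power of the frequency-normalized spectrum inside
    a band, plus the mean normalized band power.

    Ties between equal maxima break toward the lower frequency (argmax of
    the first occurrence).
    """
    lo, hi = band_hz
    f = spectrum.freqs_hz
    if lo < f[0] or hi > f[-1]:
        raise ValueError(f"band {band_hz} outside spectrum support [{f[0]}, {f[-1]}] Hz")
    spec = spectrum if spectrum.normalized else normalize_1f(spectrum)
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band_hz}")
    sub_f = f[mask]
    sub_p = spec.power[mask]
    i = int(np.argmax(sub_p))
    return BandPeak(float(sub_f[i]), float(sub_p[i]), float(sub_p.mean()))


def coherence(
    x: Signal,
    y: Signal,
    epochs: EpochSet | None = None,
    peak_band_hz: tuple[float, float] = (1.0, 10.0),
) -> tuple[CoherenceSpectrum, tuple[float, float]]:
    """Welch magnitude-squared coherence pooled over epoch segments.

    Windows of ``0.5 * fs`` samples (50% overlap, Hann) are zero-padded to
    ``10 * fs`` points before the transform. Auto- and cross-spectra are
    pooled across epoch segments, weighted by each segment's window count.
    Returns the coherence spectrum and ``(peak_coherence, peak_freq_hz)``
    within ``peak_band_hz``.
    """
    if x.fs != y.fs:
        raise ValueError(f"sampling rates differ: {x.fs} vs {y.fs} Hz")
    if x.n != y.n:
        raise ValueError("signals must share duration")
    fs = x.fs
    if epochs is None:
        epochs = EpochSet(((x.t0, x.t0 + x.duration),))
    nperseg = int(round(0.5 * fs))
    noverlap = nperseg // 2
    nfft = int(round(10 * fs))
    step = nperseg - noverlap

    sxx = syy = None
    sxy = None
    total_w = 0
    for seg_x, seg_y in zip(mask_epochs(x, epochs), mask_epochs(y, epochs)):
        if seg_x.size < nperseg:
            continue
        n_windows = 1 + (seg_x.size - nperseg) // step
        kw = dict(fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
                  nfft=nfft, detrend="constant")
        f, pxx = sps.welch(seg_x, **kw)
        _, pyy = sps.welch(seg_y, **kw)
        _, pxy = sps.csd(seg_x, seg_y, **kw)
        w = n_windows
        sxx = pxx * w if sxx is None else sxx + pxx * w
        syy = pyy * w if syy is None else syy + pyy * w
        sxy = pxy * w if sxy is None else sxy + pxy * w
        total_w += w
    if total_w == 0:
        raise InsufficientDataError(
            f"no epoch contains a full {nperseg / fs:.2f} s coherence window"
        )
    den = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(den > 0, np.abs(sxy) ** 2 / den, 0.0)
    spec = CoherenceSpectrum(f, coh)
    lo, hi = peak_band_hz
    mask = (f >= lo) & (f <= hi)
    i = int(np.argmax(spec.coherence[mask]))
    peak = (float(spec.coherence[mask][i]), float(f[mask][i]))
    return spec, peak
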