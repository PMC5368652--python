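"""Phase-amplitude coupling via the Kullback-Leibler modulation index.

The amplitude envelope of a fast oscillation is averaged in 18 bins of the
slow oscillation's phase (20 degrees per bin) and normalized to sum 1; the
modulation index is the Kullback-Leibler divergence of this distribution
from uniform, divided by log(18), so it ranges from 0 (no modulation) to 1
(all envelope mass in one phase bin). The comodulogram scans this index
over a grid of slow (phase-giving) and fast (amplitude-giving) filter
bands, computed in non-overlapping 4 s windows inside the analysis epochs
and averaged across windows.

Theta-rich epochs are extracted by thresholding the sliding rms of the
theta-filtered trace at its mean plus two standard deviations; restricting
the comodulogram to those epochs tests whether slow-rhythm-gamma coupling
survives during strong theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import (
    wrap_phase,
    N_PHASE_BINS,
    PHASE_BIN_CENTERS,
    PHASE_BIN_EDGES,
    AmplitudeSeries,
    DegenerateSignalError,
    EpochSet,
    InsufficientDataError,
    PhaseSeries,
    Signal,
    analytic_amplitude,
    analytic_phase,
    bandpass,
    epoch_sample_slices,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseAmplitudeDistribution",
    "Comodulogram",
    "PreferredPhase",
    "modulation_index",
    "comodulogram",
    "preferred_coupling_phase",
    "extract_theta_epochs",
    "pac_in_theta_epochs",
    "band_modulation_index",
]


@dataclass(frozen=True)
class PhaseAmplitudeDistribution:
    """Normalized mean envelope per 20-degree phase bin."""

    bin_centers: np.ndarray
    mean_amp: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.mean_amp, dtype=float)
        if p.min() < -1e-12 or not np.isclose(p.sum(), 1.0):
            raise ValueError("mean_amp must be non-negative and sum to 1")
        object.__setattr__(self, "mean_amp", np.clip(p, 0.0, None))
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))


@dataclass(frozen=True)
class Comodulogram:
    """Modulation-index matrix over (phase frequency x amplitude frequency)."""

    phase_freqs_hz: np.ndarray       # band centers of the slow filters
    amp_freqs_hz: np.ndarray         # band centers of the fast filters
    mi: np.ndarray                   # (n_phase, n_amp)
    distributions: np.ndarray | None = None  # (n_phase, n_amp, 18)
    phase_bandwidth_hz: float = 1.0
    amp_bandwidth_hz: float = 10.0
    n_windows: int = 0

    def __post_init__(self) -> None:
        mi = np.asarray(self.mi, dtype=float)
        if mi.shape != (len(self.phase_freqs_hz), len(self.amp_freqs_hz)):
            raise ValueError("mi matrix shape must be (n_phase_freqs, n_amp_freqs)")
        if mi.size and (np.nanmin(mi) < -1e-12 or np.nanmax(mi) > 1 + 1e-12):
            raise ValueError("modulation indices must lie in [0, 1]")
        object.__setattr__(self, "mi", mi)

    def band_max(
        self, phase_band_hz: tuple[float, float],
        amp_band_hz: tuple[float, float] | None = None,
    ) -> float:
        """Maximum MI over grid cells whose phase (and optionally amplitude)
        center falls inside the given band(s)."""
        pmask = (self.phase_freqs_hz >= phase_band_hz[0]) & (
            self.phase_freqs_hz <= phase_band_hz[1])
        if not pmask.any():
            raise ValueError(f"no phase-frequency bins inside {phase_band_hz}")
        sub = self.mi[pmask]
        if amp_band_hz is not None:
            amask = (self.amp_freqs_hz >= amp_band_hz[0]) & (
                self.amp_freqs_hz <= amp_band_hz[1])
            sub = sub[:, amask]
        return float(np.nanmax(sub))

    def argmax(self) -> tuple[float, float]:
        """(phase_freq, amp_freq) of the maximal MI."""
        i, j = np.unravel_index(int(np.nanargmax(self.mi)), self.mi.shape)
        return float(self.phase_freqs_hz[i]), float(self.amp_freqs_hz[j])


class PreferredPhase(NamedTuple):
    phase_rad: float
    resultant_length: float
    defined: bool


def _mi_from_distribution(p: np.ndarray) -> float:
    """KL(p || uniform) / log(N) with the x*log(x) -> 0 convention."""
    n = p.size
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n)))
    return kl / np.log(n)


def modulation_index(
    phase: PhaseSeries | np.ndarray,
    amplitude: AmplitudeSeries | np.ndarray,
    n_bins: int = N_PHASE_BINS,
) -> tuple[float, PhaseAmplitudeDistribution]:
    """Kullback-Leibler modulation index of an envelope over a phase series.

    Returns ``(mi, distribution)`` where the distribution is the normalized
    mean envelope per phase bin. Phase bins containing no samples carry
    zero mass (the x*log x -> 0 convention keeps the divergence finite).
    """
    phi = phase.phase if isinstance(phase, PhaseSeries) else np.asarray(phase, dtype=float)
    amp = (amplitude.envelope if isinstance(amplitude, AmplitudeSeries)
           else np.asarray(amplitude, dtype=float))
    if phi.size != amp.size:
        raise ValueError("phase and amplitude must have equal length")
    if phi.size == 0:
        raise InsufficientDataError("empty input")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, phi, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mean_amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = mean_amp.sum()
    if total <= 0:
        raise DegenerateSignalError("zero total amplitude: distribution undefined")
    p = mean_amp / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    return _mi_from_distribution(p), PhaseAmplitudeDistribution(centers, p)


def _window_slices(signal: Signal, epochs: EpochSet, window_s: float) -> list[slice]:
    """Non-overlapping complete windows inside the epochs (never spanning
    an epoch boundary)."""
    nw = int(round(window_s * signal.fs))
    out = []
    for sl in epoch_sample_slices(signal, epochs):
        n_full = (sl.stop - sl.start) // nw
        for k in range(n_full):
            out.append(slice(sl.start + k * nw, sl.start + (k + 1) * nw))
    return out


def comodulogram(
    signal: Signal,
    epochs: EpochSet | None = None,
    window_s: float = 4.0,
    phase_freqs_hz: np.ndarray | None = None,
    amp_freqs_hz: np.ndarray | None = None,
    phase_bandwidth_hz: float = 1.0,
    amp_bandwidth_hz: float = 10.0,
    keep_distributions: bool = False,
) -> Comodulogram:
    """Modulation-index comodulogram over a grid of (slow, fast) bands.

    Defaults follow the standard scan: slow bands centered 2-10 Hz (1 Hz
    bandwidth, 1 Hz steps), fast bands centered 30-150 Hz (10 Hz bandwidth,
    1 Hz steps). For every band pair the full trace is filtered, Hilbert
    phase/envelope extracted, and the MI computed per non-overlapping
    ``window_s`` window inside the epochs, then averaged across windows.
    """
    if epochs is None:
        epochs = EpochSet(((signal.t0, signal.t0 + signal.duration),))
    if phase_freqs_hz is None:
        phase_freqs_hz = np.arange(2.0, 10.0 + 1e-9, 1.0)
    if amp_freqs_hz is None:
        amp_freqs_hz = np.arange(30.0, 150.0 + 1e-9, 1.0)
    phase_freqs_hz = np.asarray(phase_freqs_hz, dtype=float)
    amp_freqs_hz = np.asarray(amp_freqs_hz, dtype=float)

    slices = _window_slices(signal, epochs, window_s)
    if not slices:
        raise InsufficientDataError(
            f"no epoch contains a complete {window_s} s window"
        )
    n_win = len(slices)
    # sample -> window index map (only samples inside windows are used)
    widx = np.full(signal.n, -1, dtype=int)
    for w, sl in enumerate(slices):
        widx[sl] = w
    used = widx >= 0
    widx_used = widx[used]

    nP, nA = phase_freqs_hz.size, amp_freqs_hz.size
    mi = np.zeros((nP, nA))
    dists = np.zeros((nP, nA, N_PHASE_BINS)) if keep_distributions else None

    envelopes = []
    for fa in amp_freqs_hz:
        band = (fa - amp_bandwidth_hz / 2, fa + amp_bandwidth_hz / 2)
        env = analytic_amplitude(bandpass(signal, *band), band).envelope
        envelopes.append(env[used])

    nbins = N_PHASE_BINS
    for i, fp in enumerate(phase_freqs_hz):
        band = (fp - phase_bandwidth_hz / 2, fp + phase_bandwidth_hz / 2)
        phi = analytic_phase(bandpass(signal, *band), band).phase[used]
        bidx = np.clip(
            np.searchsorted(PHASE_BIN_EDGES, phi, side="right") - 1, 0, nbins - 1
        )
        flat = widx_used * nbins + bidx
        counts = np.bincount(flat, minlength=n_win * nbins).reshape(n_win, nbins)
        for j in range(nA):
            sums = np.bincount(
                flat, weights=envelopes[j], minlength=n_win * nbins
            ).reshape(n_win, nbins)
            mean_amp = np.divide(
                sums, counts, out=np.zeros_like(sums), where=counts > 0
            )
            totals = mean_amp.sum(axis=1, keepdims=True)
            p = np.divide(mean_amp, totals, out=np.zeros_like(mean_amp),
                          where=totals > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(p > 0, p * np.log(p * nbins), 0.0)
            mi[i, j] = terms.sum(axis=1).mean() / np.log(nbins)
            if keep_distributions:
                mean_p = p.mean(axis=0)
                s = mean_p.sum()
                dists[i, j] = mean_p / s if s > 0 else mean_p
    return Comodulogram(
        phase_freqs_hz, amp_freqs_hz, mi, dists,
        phase_bandwidth_hz, amp_bandwidth_hz, n_windows=n_win,
    )


def preferred_coupling_phase(distribution: PhaseAmplitudeDistribution) -> PreferredPhase:
    """Circular mean of the phase-bin centers weighted by the normalized
    envelope distribution; flagged undefined when the weighted resultant
    vector nearly vanishes (e.g. uniform or antipodal distributions)."""
    vec = np.sum(distribution.mean_amp * np.exp(1j * distribution.bin_centers))
    r = float(np.abs(vec))
    if r < 1e-6:
        return PreferredPhase(np.nan, r, False)
    return PreferredPhase(float(wrap_phase(np.angle(vec))), r, True)


def extract_theta_epochs(
    signal: Signal,
    rms_window_s: float = 0.5,
    band_hz: tuple[float, float] = (6.0, 12.0),
    threshold_sd: float = 2.0,
    overlap: float = 0.5,
) -> EpochSet:
    """Epochs of pronounced theta power.

    The trace is theta-filtered, a sliding rms (window ``rms_window_s``,
    50% overlap) is computed, and windows whose rms exceeds the series
    mean plus ``threshold_sd`` standard deviations are kept; adjacent
    detections closer than one window are merged.
    """
    if signal.duration < 10.0:
        raise InsufficientDataError("need at least 10 s to calibrate the rms threshold")
    theta = bandpass(signal, *band_hz)
    x2 = theta.samples**2
    if not np.any(x2):
        raise DegenerateSignalError("flat signal has no theta-band power")
    nw = int(round(rms_window_s * signal.fs))
    hop = max(int(round(nw * (1 - overlap))), 1)
    cs = np.concatenate([[0.0], np.cumsum(x2)])
    starts = np.arange(0, x2.size - nw + 1, hop)
    rms = np.sqrt((cs[starts + nw] - cs[starts]) / nw)
    thresh = rms.mean() + threshold_sd * rms.std()
    if rms.std() == 0:
        raise DegenerateSignalError("rms series is constant; threshold undefined")
    hot = rms > thresh
    t = signal.t0 + starts / signal.fs
    intervals = [(t[i], t[i] + rms_window_s) for i in np.flatnonzero(hot)]
    return EpochSet.merged(intervals, max_gap_s=rms_window_s)


def band_modulation_index(
    signal: Signal,
    epochs: EpochSet | None = None,
    phase_band_hz: tuple[float, float] = (1.0, 5.0),
    amp_band_hz: tuple[float, float] = (80.0, 100.0),
    window_s: float = 4.0,
) -> tuple[float, PhaseAmplitudeDistribution]:
    """Single-band MI with the phase filter applied over the full band
    (e.g. the 1-5 Hz slow rhythm) rather than the 1 Hz comodulogram steps;
    MI is averaged across non-overlapping windows and the pooled
    phase-amplitude distribution is returned alongside."""
    if epochs is None:
        epochs = EpochSet(((signal.t0, signal.t0 + signal.duration),))
    phi = analytic_phase(bandpass(signal, *phase_band_hz), phase_band_hz)
    env = analytic_amplitude(bandpass(signal, *amp_band_hz), amp_band_hz)
    slices = _window_slices(signal, epochs, window_s)
    if not slices:
        raise InsufficientDataError(f"no complete {window_s} s window in epochs")
    mis = []
    pooled = np.zeros(N_PHASE_BINS)
    for sl in slices:
        mi, dist = modulation_index(phi.phase[sl], env.envelope[sl])
        mis.append(mi)
        pooled += dist.mean_amp
    pooled /= pooled.sum()
    return float(np.mean(mis)), PhaseAmplitudeDistribution(PHASE_BIN_CENTERS, pooled)


def pac_in_theta_epochs(
    signal: Signal,
    theta_epochs: EpochSet,
    window_s: float = 4.0,
    prr_band_hz: tuple[float, float] = (1.0, 5.0),
    theta_band_hz: tuple[float, float] = (6.0, 12.0),
    **comod_kwargs,
) -> tuple[Comodulogram, dict]:
    """Comodulogram restricted to theta-rich epochs and the ratio of
    slow-rhythm-gamma to theta-gamma coupling.

    Band MIs are comodulogram maxima over grid rows whose phase-frequency
    center falls in the slow-rhythm band (clipped to the grid's 2 Hz lower
    edge) and the theta band. If no complete ``window_s`` window fits in
    the epochs the window is shortened to the longest epoch (logged; a
    departure from the standard 4 s window).
    """
    if len(theta_epochs) == 0:
        raise InsufficientDataError("theta epoch set is empty")
    longest = max(b - a for a, b in theta_epochs)
    eff_window = window_s
    if longest < window_s:
        eff_window = longest
        logger.warning(
            "no theta epoch fits the %.1f s window; shortening to %.2f s",
            window_s, eff_window,
        )
    comod = comodulogram(signal, theta_epochs, window_s=eff_window, **comod_kwargs)
    mi_prr = comod.band_max(prr_band_hz)
    mi_theta = comod.band_max(theta_band_hz)
    ratio = mi_prr / mi_theta if mi_theta > 0 else np.inf
    return comod, {
        "mi_prr": mi_prr,
        "mi_theta": mi_theta,
        "ratio": float(ratio),
        "window_s": eff_window,
    }
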