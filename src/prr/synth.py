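"""Synthetic session generator.

Produces surrogate recordings with the statistical structure of awake-mouse
prefrontal LFP during immobile epochs with regular nasal breathing:

* an irregular quasi-periodic respiration trace (~3.5 Hz, per-cycle period
  jitter with a configurable coefficient of variation),
* an LFP composed of (a) a respiration-locked slow component, (b) a theta
  component locked at an integer cycle ratio (default 2:1) to the slow
  rhythm with von Mises phase jitter, (c) band-limited gamma whose
  amplitude envelope is modulated by the slow rhythm's phase, and
  (d) 1/f^alpha Gaussian background noise,
* spike trains drawn from inhomogeneous Poisson processes whose intensity
  follows a von Mises tuning curve on a chosen rhythm's phase, with an
  absolute refractory period, and biphasic mean spike waveforms whose
  half-duration / trough-to-peak times follow the reported group means of
  putative pyramidal cells and interneurons.

Every generated object is a deterministic function of (parameters, seed),
and the full parameter record travels with the session as ground truth, so
each analysis stage has a recovery test against known structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import EpochSet, Signal, analytic_phase, bandpass, wrap_phase, zscore
from .units import SpikeTrain

__all__ = [
    "UnitParams",
    "GroundTruth",
    "SessionConfig",
    "SyntheticSession",
    "generate_respiration",
    "generate_lfp",
    "generate_spike_train",
    "generate_waveform",
    "generate_session",
    "PYR_TEMPLATE",
    "IN_TEMPLATE",
]

# Waveform template parameters (ms): reported group means of the two classes.
PYR_TEMPLATE = {"half_duration_ms": 0.47, "trough_to_peak_ms": 0.31}
IN_TEMPLATE = {"half_duration_ms": 0.25, "trough_to_peak_ms": 0.20}

# Reported mean firing rates (Hz) used as generator defaults.
PYR_RATE_HZ = 1.7
IN_RATE_HZ = 9.4

# Reported preferred firing phases (rad) on the slow rhythm.
PYR_PREFERRED_PHASE = -0.89
IN_PREFERRED_PHASE = 1.34


@dataclass(frozen=True)
class UnitParams:
    """Ground-truth parameters of one simulated unit."""

    label: str                      # "PYR" or "IN"
    rate_hz: float
    coupled_rhythm: str | None      # "prr", "theta", "respiration" or None
    preferred_phase_rad: float
    kappa: float
    half_duration_ms: float
    trough_to_peak_ms: float


@dataclass(frozen=True)
class GroundTruth:
    """Full parameter record of a synthetic session.

    Amplitudes are expressed in units of the background-noise SD (the
    1/f background is normalized to unit variance before mixing).
    """

    respiration_freq_hz: float = 3.5
    respiration_cv: float = 0.1
    prr_amp: float = 2.0
    prr_lag_rad: float = 0.0
    theta_freq_ratio: int = 2
    theta_lock_kappa: float = 4.0
    theta_amp: float = 1.0
    gamma_band_hz: tuple[float, float] = (80.0, 100.0)
    gamma_amp: float = 0.5
    pac_depth: float = 0.5
    pac_preferred_phase_rad: float = 0.0
    noise_exponent: float = 1.5
    unit_params: tuple[UnitParams, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ValueError("pac_depth must lie in [0, 1]")
        if self.theta_lock_kappa < 0:
            raise ValueError("theta_lock_kappa must be non-negative")
        if not (isinstance(self.theta_freq_ratio, (int, np.integer)) and self.theta_freq_ratio >= 1):
            raise ValueError("theta_freq_ratio must be a positive integer")
        if any(u.kappa < 0 for u in self.unit_params):
            raise ValueError("unit kappas must be non-negative")


@dataclass(frozen=True)
class SessionConfig:
    """Study-condition parameters of one simulated session."""

    duration_s: float = 300.0
    fs: float = 1000.0
    n_pyr: int = 10
    n_in: int = 3
    pyr_rate_hz: float = PYR_RATE_HZ
    in_rate_hz: float = IN_RATE_HZ
    pyr_coupled_fraction: float = 0.26   # share of PYR units entrained in vivo
    in_coupled_fraction: float = 0.58
    coupled_rhythm: str = "prr"
    unit_kappa: float = 2.0
    immobility_fraction: float = 1.0
    immobility_block_s: float = 30.0
    refractory_ms: float = 2.0
    truth: GroundTruth = field(default_factory=GroundTruth)


@dataclass(frozen=True)
class SyntheticSession:
    lfp: Signal
    respiration: Signal
    immobility: EpochSet
    spike_trains: tuple[SpikeTrain, ...]
    truth: GroundTruth

    @property
    def duration(self) -> float:
        return self.lfp.duration


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))


def _respiration_phase(
    duration_s: float, fs: float, mean_freq_hz: float, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Unwrapped respiration phase: 2*pi per breathing cycle.

    Cycle periods are i.i.d. gamma with mean 1/f and the requested CV;
    the phase advances linearly within each cycle (smooth, strictly
    increasing). cv = 0 degenerates to a strictly periodic ramp.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if cv == 0:
        return 2 * np.pi * mean_freq_hz * t
    mean_period = 1.0 / mean_freq_hz
    shape = 1.0 / cv**2
    n_cycles = int(np.ceil(duration_s / mean_period * (1 + 5 * cv))) + 10
    periods = rng.gamma(shape, mean_period / shape, size=n_cycles)
    while periods.sum() < duration_s:
        periods = np.concatenate([periods, rng.gamma(shape, mean_period / shape, size=10)])
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    cycle_phase = 2 * np.pi * np.arange(boundaries.size)
    return np.interp(t, boundaries, cycle_phase)


def generate_respiration(
    duration_s: float, fs: float, mean_freq_hz: float = 3.5, cv: float = 0.1, seed: int = 0
) -> Signal:
    """Quasi-periodic nasal airflow trace; inspiration deflects positive.

    The per-cycle instantaneous frequency has mean ``mean_freq_hz`` and
    coefficient of variation ``cv``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    if not 0.5 < mean_freq_hz < 12:
        raise ValueError("mean_freq_hz must lie in (0.5, 12) Hz")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    phi = _respiration_phase(duration_s, fs, mean_freq_hz, cv, _rng(seed, 0))
    return Signal(np.cos(phi), fs, label="respiration")


def _oneoverf_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to 1/f^exponent,
    normalized to unit variance."""
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _cycle_jitter(phi_unwrapped: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Von Mises phase jitter drawn once per slow cycle, linearly
    interpolated across cycle midpoints so the jittered phase stays smooth."""
    cycles = phi_unwrapped / (2 * np.pi)
    n_cycles = int(np.floor(cycles[-1])) + 2
    eps = rng.vonmises(0.0, kappa, size=n_cycles + 2)
    midpoints = np.arange(-1, n_cycles + 1) + 0.5
    return np.interp(cycles, midpoints, eps)


def _compose_lfp(
    duration_s: float, fs: float, truth: GroundTruth, respiration: Signal
) -> tuple[Signal, dict[str, np.ndarray]]:
    """Build the LFP mixture and return it with the generating phase series."""
    n = int(round(duration_s * fs))
    if respiration.fs != fs:
        raise ValueError(f"respiration fs {respiration.fs} != requested LFP fs {fs}")
    if respiration.n != n:
        raise ValueError("respiration duration does not match requested LFP duration")
    rng = _rng(truth.seed, 1)

    phi_resp = np.unwrap(analytic_phase(respiration).phase)
    phi_slow = phi_resp + truth.prr_lag_rad
    parts = []
    if truth.prr_amp > 0:
        parts.append(truth.prr_amp * np.cos(phi_slow))

    phases: dict[str, np.ndarray] = {
        "respiration": wrap_phase(phi_resp),
        "prr": wrap_phase(phi_slow),
    }

    # theta locked at an integer cycle ratio; kappa = 0 means "no coherent
    # theta component" (the locked relation is undefined at zero
    # concentration), so the component is omitted entirely.
    if truth.theta_amp > 0 and truth.theta_lock_kappa > 0:
        jitter = _cycle_jitter(phi_slow, truth.theta_lock_kappa, rng)
        phi_theta = truth.theta_freq_ratio * phi_slow + jitter
        parts.append(truth.theta_amp * np.cos(phi_theta))
        phases["theta"] = wrap_phase(phi_theta)

    if truth.gamma_amp > 0:
        lo, hi = truth.gamma_band_hz
        sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= carrier.std()
        envelope = 1.0 + truth.pac_depth * np.cos(phi_slow - truth.pac_preferred_phase_rad)
        parts.append(truth.gamma_amp * envelope * carrier)

    parts.append(_oneoverf_noise(n, fs, truth.noise_exponent, rng))
    lfp = zscore(Signal(np.sum(parts, axis=0), fs, label="lfp"))
    return lfp, phases


def generate_lfp(
    duration_s: float, fs: float, truth: GroundTruth, respiration: Signal
) -> Signal:
    """Synthesize a z-scored LFP trace from a respiration trace and a
    ground-truth parameter record (see module docstring for the mixture)."""
    lfp, _ = _compose_lfp(duration_s, fs, truth, respiration)
    return lfp


def generate_spike_train(
    duration_s: float,
    rate_hz: float,
    phase_series: np.ndarray | None,
    preferred_phase_rad: float = 0.0,
    kappa: float = 0.0,
    refractory_ms: float = 2.0,
    seed: int = 0,
    fs: float = 1000.0,
    unit_id: str = "unit0",
) -> SpikeTrain:
    """Phase-modulated spike train.

    An inhomogeneous Poisson process with intensity proportional to
    ``exp(kappa * cos(phi(t) - preferred_phase_rad))``, normalized so the
    pre-refractory mean rate equals ``rate_hz``, then thinned by an
    absolute refractory period. ``kappa = 0`` (or no phase series) yields a
    homogeneous Poisson process.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    refr_s = refractory_ms / 1000.0
    if rate_hz * refr_s >= 0.8:
        raise ValueError(
            f"target rate {rate_hz} Hz is unattainable with a "
            f"{refractory_ms} ms refractory period"
        )
    if duration_s <= 0:
        return SpikeTrain(unit_id, np.empty(0))
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    n = int(round(duration_s * fs))
    if kappa > 0 and phase_series is not None:
        tuning = np.exp(kappa * np.cos(phase_series[:n] - preferred_phase_rad))
        lam = rate_hz * tuning / tuning.mean()
    else:
        lam = np.full(n, rate_hz)
    # compensate the expected refractory loss so the realized rate matches
    lam = lam / (1.0 - rate_hz * refr_s)
    p = lam / fs
    candidates = np.flatnonzero(rng.random(n) < p)
    refr_samples = refr_s * fs
    times = []
    last = -np.inf
    for i in candidates:
        if i - last >= refr_samples:
            times.append(i)
            last = i
    return SpikeTrain(unit_id, np.asarray(times, dtype=float) / fs)


def generate_waveform(
    half_duration_ms: float,
    trough_to_peak_ms: float,
    waveform_fs: float = 30000.0,
    amp_noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Biphasic mean-spike template: Gaussian trough followed by a smaller
    positive peak. The two shape parameters are calibrated iteratively so
    that the *measured* features (trough width at half depth, trough to
    first subsequent local maximum) equal the requested values. Sampled on
    [-1, +2] ms."""
    from .units import _half_duration_ms  # feature extractor doubles as oracle

    t = np.arange(-1.0e-3, 2.0e-3, 1 / waveform_fs) * 1000.0  # ms
    sigma = half_duration_ms / (2 * np.sqrt(2 * np.log(2)))
    center = trough_to_peak_ms
    sigma_p = trough_to_peak_ms / 6.0
    dt_ms = 1000.0 / waveform_fs
    w = np.zeros_like(t)
    for _ in range(30):
        w = -np.exp(-(t**2) / (2 * sigma**2))
        w += 0.4 * np.exp(-((t - center) ** 2) / (2 * sigma_p**2))
        trough = int(np.argmin(w))
        half = _half_duration_ms(w, trough, waveform_fs)
        post = w[trough:]
        peaks, _ = sps.find_peaks(post, prominence=0.05 * (-w[trough]))
        peak_off = int(peaks[0]) if peaks.size else int(np.argmax(post))
        t2p = peak_off * dt_ms
        if half is None or t2p <= 0:
            break
        if abs(half - half_duration_ms) < dt_ms and abs(t2p - trough_to_peak_ms) < dt_ms:
            break
        # damped fixed-point updates; the peak cannot move left of the trough
        sigma *= (half_duration_ms / half) ** 0.5
        center = max(center - 0.5 * (t2p - trough_to_peak_ms), 2 * dt_ms)
    if amp_noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        w = w + amp_noise * rng.standard_normal(w.size)
    return w


def _immobility_epochs(duration_s: float, fraction: float, block_s: float) -> EpochSet:
    """Tile immobile intervals over the session at the requested coverage."""
    if not 0 <= fraction <= 1:
        raise ValueError("immobility_fraction must lie in [0, 1]")
    if fraction == 0:
        return EpochSet(())
    if fraction == 1:
        return EpochSet(((0.0, duration_s),))
    out = []
    start = 0.0
    while start < duration_s:
        end = min(start + fraction * block_s, duration_s)
        if end > start:
            out.append((start, end))
        start += block_s
    return EpochSet(tuple(out))


def _make_unit_params(config: SessionConfig, rng: np.random.Generator) -> tuple[UnitParams, ...]:
    units = []
    for lab, n_units, rate, frac, pref in (
        ("PYR", config.n_pyr, config.pyr_rate_hz, config.pyr_coupled_fraction,
         PYR_PREFERRED_PHASE),
        ("IN", config.n_in, config.in_rate_hz, config.in_coupled_fraction,
         IN_PREFERRED_PHASE),
    ):
        template = PYR_TEMPLATE if lab == "PYR" else IN_TEMPLATE
        n_coupled = int(round(frac * n_units))
        for k in range(n_units):
            coupled = k < n_coupled
            units.append(UnitParams(
                label=lab,
                rate_hz=rate,
                coupled_rhythm=config.coupled_rhythm if coupled else None,
                preferred_phase_rad=pref,
                kappa=config.unit_kappa if coupled else 0.0,
                half_duration_ms=template["half_duration_ms"] + 0.01 * rng.standard_normal(),
                trough_to_peak_ms=template["trough_to_peak_ms"] + 0.005 * rng.standard_normal(),
            ))
    return tuple(units)


def generate_session(config: SessionConfig, seed: int = 0) -> SyntheticSession:
    """Generate a full synthetic session: respiration, LFP, immobility
    epochs tiling the requested fraction, and spike trains with waveforms.

    Deterministic: identical (config, seed) yields a bit-identical session.
    """
    truth = replace(config.truth, seed=int(seed))
    respiration = generate_respiration(
        config.duration_s, config.fs,
        truth.respiration_freq_hz, truth.respiration_cv, seed=truth.seed,
    )
    unit_params = _make_unit_params(config, _rng(seed, 2))
    truth = replace(truth, unit_params=unit_params)
    lfp, phases = _compose_lfp(config.duration_s, config.fs, truth, respiration)
    immobility = _immobility_epochs(
        config.duration_s, config.immobility_fraction, config.immobility_block_s
    )
    trains = []
    for k, up in enumerate(unit_params):
        phase = phases.get(up.coupled_rhythm) if up.coupled_rhythm else None
        train = generate_spike_train(
            config.duration_s, up.rate_hz, phase,
            up.preferred_phase_rad, up.kappa,
            refractory_ms=config.refractory_ms,
            seed=_rng(seed, 3, k), fs=config.fs,
            unit_id=f"unit{k}",
        )
        wf = generate_waveform(
            up.half_duration_ms, up.trough_to_peak_ms,
            amp_noise=0.0,
        )
        trains.append(replace(train, waveform=wf))
    return SyntheticSession(lfp, respiration, immobility, tuple(trains), truth)
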