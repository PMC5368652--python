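"""Kullback-Leibler modulation index, comodulogram, preferred phase and
theta-rich epoch extraction."""

import numpy as np
import pytest

from prr.core import (
    DegenerateSignalError,
    EpochSet,
    InsufficientDataError,
    PHASE_BIN_CENTERS,
    Signal,
)
from prr.pac import (
    PhaseAmplitudeDistribution,
    band_modulation_index,
    comodulogram,
    extract_theta_epochs,
    modulation_index,
    pac_in_theta_epochs,
    preferred_coupling_phase,
)
from prr.synth import GroundTruth, generate_lfp, generate_respiration


def uniform_phases(n: int, seed: int = 0) -> np.ndarray:
    return np.random.default_rng(seed).uniform(-np.pi, np.pi, n)


class TestModulationIndex:
    def test_constant_envelope_gives_exact_zero(self):
        phi = uniform_phases(100000)
        mi, _ = modulation_index(phi, np.ones_like(phi))
        assert mi == 0.0

    def test_point_mass_gives_exact_one(self):
        phi = np.zeros(100)
        mi, _ = modulation_index(phi, np.ones(100))
        assert mi == pytest.approx(1.0, abs=1e-12)

    def test_cosine_envelope_matches_closed_form(self):
        # KL of the 18-bin discretization of (1 + 0.5 cos(phi))/(2 pi),
        # computed in closed form from the per-bin integrals
        phi = np.linspace(-np.pi, np.pi, 1_000_001)[:-1]
        mi, _ = modulation_index(phi, 1 + 0.5 * np.cos(phi))
        assert mi == pytest.approx(0.0221290, abs=1e-4)

    def test_invariances(self):
        rng = np.random.default_rng(1)
        phi = uniform_phases(50000, seed=2)
        env = 1 + 0.4 * np.cos(phi) + 0.05 * rng.random(phi.size)
        mi0, _ = modulation_index(phi, env)
        mi_scaled, _ = modulation_index(phi, 7.3 * env)
        assert mi_scaled == pytest.approx(mi0, abs=1e-12)
        rotated = np.mod(phi + 1.0 + np.pi, 2 * np.pi) - np.pi
        env_rot = 1 + 0.4 * np.cos(rotated - 1.0) + 0.05 * rng.random(phi.size)
        mi_rot, _ = modulation_index(rotated, env_rot)
        assert abs(mi_rot - mi0) < 0.005  # statistically identical setup

    def test_identical_windows_give_identical_mi(self):
        phi = uniform_phases(4000, seed=3)
        env = 1 + 0.5 * np.cos(phi)
        mi1, _ = modulation_index(phi, env)
        mi2, _ = modulation_index(phi.copy(), env.copy())
        assert mi1 == mi2

    def test_zero_amplitude_rejected(self):
        with pytest.raises(DegenerateSignalError):
            modulation_index(uniform_phases(100), np.zeros(100))


class TestComodulogram:
    def test_recovers_generator_coupling_location(self):
        resp = generate_respiration(120, 1000, 3.5, 0.1, seed=4)
        lfp = generate_lfp(120, 1000, GroundTruth(pac_depth=0.5), resp)
        comod = comodulogram(
            lfp, phase_freqs_hz=np.arange(2.0, 9.0),
            amp_freqs_hz=np.arange(40.0, 141.0, 5.0))
        fp, fa = comod.argmax()
        assert 3.0 <= fp <= 4.0
        assert 75.0 <= fa <= 105.0

    def test_no_coupling_stays_below_null_band(self):
        null_max = []
        for seed in range(21):
            resp = generate_respiration(60, 1000, 3.5, 0.1, seed=200 + seed)
            lfp = generate_lfp(60, 1000, GroundTruth(pac_depth=0.0), resp)
            mi, _ = band_modulation_index(lfp)
            null_max.append(mi)
        probe, bank = null_max[0], np.asarray(null_max[1:])
        assert probe < np.quantile(bank, 0.95) * 2  # same distribution

    def test_mi_monotonic_in_modulation_depth(self):
        depths = [0.0, 0.1, 0.25, 0.5, 1.0]
        means = []
        for depth in depths:
            vals = []
            for seed in range(10):
                resp = generate_respiration(60, 1000, 3.5, 0.1, seed=300 + seed)
                lfp = generate_lfp(
                    60, 1000, GroundTruth(pac_depth=depth), resp)
                mi, _ = band_modulation_index(lfp)
                vals.append(mi)
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_insufficient_window_rejected(self):
        resp = generate_respiration(10, 1000, 3.5, 0.1, seed=5)
        lfp = generate_lfp(10, 1000, GroundTruth(), resp)
        with pytest.raises(InsufficientDataError):
            comodulogram(lfp, EpochSet(((0, 2),)),
                         phase_freqs_hz=np.array([3.0]),
                         amp_freqs_hz=np.array([90.0]))


class TestPreferredPhase:
    def test_single_bin_mass(self):
        p = np.zeros(18)
        p[9] = 1.0  # bin centered just above 0
        dist = PhaseAmplitudeDistribution(PHASE_BIN_CENTERS, p)
        pref = preferred_coupling_phase(dist)
        assert pref.defined
        assert pref.phase_rad == pytest.approx(PHASE_BIN_CENTERS[9])

    def test_antipodal_mass_is_undefined(self):
        p = np.zeros(18)
        # +pi/2 and -pi/2 are 9 bins apart: exactly antipodal centers
        p[4] = 0.5
        p[13] = 0.5
        dist = PhaseAmplitudeDistribution(PHASE_BIN_CENTERS, p)
        assert not preferred_coupling_phase(dist).defined

    def test_cosine_distribution_recovers_offset(self):
        phi = np.linspace(-np.pi, np.pi, 500001)[:-1]
        _, dist = modulation_index(phi, 1 + 0.5 * np.cos(phi - 1.0))
        pref = preferred_coupling_phase(dist)
        assert pref.phase_rad == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("target", [-np.pi / 2, 0.0, np.pi / 2, np.pi])
    def test_generator_phase_recovery_sweep(self, target):
        errs = []
        for seed in range(10):
            resp = generate_respiration(60, 1000, 3.5, 0.1, seed=400 + seed)
            truth = GroundTruth(pac_depth=0.5, pac_preferred_phase_rad=target)
            lfp = generate_lfp(60, 1000, truth, resp)
            _, dist = band_modulation_index(lfp)
            pref = preferred_coupling_phase(dist)
            err = np.angle(np.exp(1j * (pref.phase_rad - target)))
            errs.append(err)
        assert abs(np.mean(errs)) < 0.15


class TestThetaEpochs:
    @staticmethod
    def _noise(duration_s: float, seed: int, fs: float = 1000.0) -> Signal:
        rng = np.random.default_rng(seed)
        n = int(duration_s * fs)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        amp = np.zeros_like(freqs)
        amp[1:] = freqs[1:] ** -0.75
        spec = amp * (rng.standard_normal(freqs.size)
                      + 1j * rng.standard_normal(freqs.size))
        x = np.fft.irfft(spec, n=n)
        return Signal(x / x.std(), fs)

    def test_stationary_noise_detects_little(self):
        # the mean+2SD threshold on the right-skewed rms series marks a few
        # percent of windows; 0.5 s windows at 0.25 s hop roughly double
        # the time coverage of isolated detections
        sig = self._noise(600, seed=6)
        eps = extract_theta_epochs(sig)
        assert eps.total_duration / 600 < 0.08

    def test_bursts_recovered_and_total_bounded(self):
        sig = self._noise(600, seed=7)
        x = sig.samples.copy()
        # theta-band background scale sets the burst amplitude
        from prr.core import bandpass
        sd_theta = bandpass(sig, 6, 12).samples.std()
        t = np.arange(x.size) / 1000
        burst_starts = [100.0, 300.0, 500.0]  # 3 x 2 s = 1% of 600 s
        burst_mask = np.zeros(x.size, dtype=bool)
        for b in burst_starts:
            sl = slice(int(b * 1000), int((b + 2) * 1000))
            x[sl] += 5 * sd_theta * np.sqrt(2) * np.sin(2 * np.pi * 8 * t[sl])
            burst_mask[sl] = True
        eps = extract_theta_epochs(Signal(x, 1000))
        detected = np.zeros(x.size, dtype=bool)
        for a, b in eps:
            detected[int(a * 1000):int(b * 1000)] = True
        recovery = (detected & burst_mask).sum() / burst_mask.sum()
        assert recovery >= 0.8
        assert eps.total_duration / 600 < 0.02

    def test_stationary_strong_theta_self_adapts(self):
        t = np.arange(600000) / 1000
        rng = np.random.default_rng(8)
        x = 5 * np.sin(2 * np.pi * 8 * t) + rng.standard_normal(t.size)
        eps = extract_theta_epochs(Signal(x, 1000))
        assert eps.total_duration / 600 < 0.1

    def test_flat_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            extract_theta_epochs(Signal(np.zeros(20000), 1000))

    def test_short_signal_rejected(self):
        with pytest.raises(InsufficientDataError):
            extract_theta_epochs(Signal(np.ones(2000), 1000))


class TestThetaRestrictedPac:
    @staticmethod
    def _construct(drive: str, seed: int = 9) -> Signal:
        """Gamma amplitude driven by the slow rhythm's or theta's phase."""
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        rng = np.random.default_rng(seed)
        # incommensurate frequencies: an exact 2:1 ratio would phase-lock
        # theta to the slow rhythm and let PAC leak between the bands
        slow_phase = 2 * np.pi * 3.5 * t
        theta_phase = 2 * np.pi * 7.3 * t
        drive_phase = slow_phase if drive == "slow" else theta_phase
        from scipy.signal import butter, sosfiltfilt
        sos = butter(2, [80, 100], btype="bandpass", fs=fs, output="sos")
        carrier = sosfiltfilt(sos, rng.standard_normal(t.size))
        carrier /= carrier.std()
        x = (2 * np.cos(slow_phase) + 1.0 * np.cos(theta_phase)
             + 0.5 * (1 + 0.8 * np.cos(drive_phase)) * carrier
             + 0.5 * rng.standard_normal(t.size))
        return Signal(x, fs)

    @pytest.mark.parametrize("drive,expect_gt_one", [("slow", True), ("theta", False)])
    def test_ratio_reflects_driving_rhythm(self, drive, expect_gt_one):
        sig = self._construct(drive)
        theta_epochs = EpochSet(((2.0, 58.0),))
        _, report = pac_in_theta_epochs(
            sig, theta_epochs,
            phase_freqs_hz=np.arange(2.0, 9.0),
            amp_freqs_hz=np.arange(70.0, 111.0, 10.0))
        assert (report["ratio"] > 1) == expect_gt_one

    def test_short_epochs_shrink_window(self):
        sig = self._construct("slow")
        theta_epochs = EpochSet(((2.0, 4.5), (10.0, 12.5)))
        _, report = pac_in_theta_epochs(
            sig, theta_epochs,
            phase_freqs_hz=np.array([3.0, 7.0]),
            amp_freqs_hz=np.array([90.0]))
        assert report["window_s"] == pytest.approx(2.5)

    def test_empty_epochs_rejected(self):
        sig = self._construct("slow")
        with pytest.raises(InsufficientDataError):
            pac_in_theta_epochs(sig, EpochSet(()))
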