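"""Waveform classification, firing rates and spike-phase entrainment."""

import numpy as np
import pytest

from prr.circular import circular_mean, vonmises_R
from prr.core import EpochSet, InsufficientDataError, PhaseSeries, wrap_phase
from prr.synth import IN_TEMPLATE, PYR_TEMPLATE, generate_waveform
from prr.units import (
    SpikeTrain,
    classify_unit,
    firing_rate,
    population_summary,
    rayleigh_test,
    spike_phases,
    unit_coupling,
)


def phase_of_tone(freq_hz: float, duration_s: float, fs: float = 1000.0) -> PhaseSeries:
    t = np.arange(int(duration_s * fs)) / fs
    return PhaseSeries(wrap_phase(2 * np.pi * freq_hz * t), fs, None)


class TestClassifyUnit:
    def test_group_mean_templates_classified(self):
        pyr = classify_unit(generate_waveform(**PYR_TEMPLATE), 30000, 1.7)
        assert pyr.label == "PYR"
        assert pyr.half_duration_ms == pytest.approx(0.47, abs=0.04)
        inn = classify_unit(generate_waveform(**IN_TEMPLATE), 30000, 9.4)
        assert inn.label == "IN"
        assert inn.trough_to_peak_ms == pytest.approx(0.20, abs=0.04)

    def test_positive_going_waveform_unclassifiable(self):
        w = -generate_waveform(**PYR_TEMPLATE)
        assert classify_unit(w, 30000, 1.0).label == "unclassifiable"

    def test_trough_at_edge_unclassifiable(self):
        w = np.linspace(-1.0, 0.5, 90)  # global minimum at sample 0
        assert classify_unit(w, 30000, 1.0).label == "unclassifiable"

    def test_noisy_templates_accuracy(self):
        rng = np.random.default_rng(0)
        correct = 0
        n = 100
        for k in range(n):
            tpl, lab = (PYR_TEMPLATE, "PYR") if k % 2 else (IN_TEMPLATE, "IN")
            w = generate_waveform(**tpl, amp_noise=0.05, rng=rng)
            correct += classify_unit(w, 30000, 1.0).label == lab
        assert correct / n >= 0.95

    def test_session_labels_recovered_exactly(self, short_session):
        for train, up in zip(short_session.spike_trains,
                             short_session.truth.unit_params):
            got = classify_unit(train.waveform, train.waveform_fs, 1.0)
            assert got.label == up.label


class TestFiringRate:
    def test_uniform_spikes(self):
        train = SpikeTrain("u", np.linspace(0.25, 49.75, 100))
        assert firing_rate(train, EpochSet(((0, 50),))) == pytest.approx(2.0)

    def test_no_spikes(self):
        assert firing_rate(SpikeTrain("u", np.empty(0)), EpochSet(((0, 10),))) == 0.0

    def test_empty_epochs_rejected(self):
        with pytest.raises(ValueError):
            firing_rate(SpikeTrain("u", np.array([1.0])), EpochSet(()))

    def test_poisson_rate_recovered(self, short_session):
        # IN units carry the high generator rate
        in_trains = [t for t, up in zip(short_session.spike_trains,
                                        short_session.truth.unit_params)
                     if up.label == "IN"]
        rates = [firing_rate(t, short_session.immobility) for t in in_trains]
        assert np.mean(rates) == pytest.approx(9.4, abs=0.9)


class TestSpikePhases:
    def test_spikes_at_peaks_read_zero_phase(self):
        phi = phase_of_tone(3.5, 60.0)
        peaks = np.arange(0, 60, 1 / 3.5)[1:-1]  # cosine peak times
        train = SpikeTrain("u", peaks)
        phases = spike_phases(train, phi, EpochSet(((0, 60),)))
        assert np.abs(phases).max() < 0.05

    def test_spikes_at_troughs_read_pi(self):
        phi = phase_of_tone(3.5, 60.0)
        troughs = np.arange(0, 60, 1 / 3.5)[1:-1] + 0.5 / 3.5
        phases = spike_phases(SpikeTrain("u", troughs), phi, EpochSet(((0, 60),)))
        assert np.abs(np.abs(phases) - np.pi).max() < 0.05

    def test_empty_epochs_give_empty_list(self):
        phi = phase_of_tone(3.5, 10.0)
        out = spike_phases(SpikeTrain("u", np.array([1.0, 2.0])), phi, EpochSet(()))
        assert out.size == 0

    def test_epoch_restriction(self):
        phi = phase_of_tone(3.5, 10.0)
        train = SpikeTrain("u", np.array([1.0, 5.0, 9.0]))
        out = spike_phases(train, phi, EpochSet(((4, 6),)))
        assert out.size == 1


class TestRayleigh:
    def test_known_small_sample(self):
        # mean vector of [0, pi/2, 0, -pi/2, 0] is (0.6, 0)
        R, z, _ = rayleigh_test(np.array([0, np.pi / 2, 0, -np.pi / 2, 0]))
        assert R == pytest.approx(0.6)
        assert z == pytest.approx(1.8)

    def test_perfect_concentration(self):
        R, _, p = rayleigh_test(np.full(20, 1.3))
        assert R == pytest.approx(1.0)
        assert p < 1e-6

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        phases = rng.vonmises(0.5, 1.0, 200)
        _, z, p = rayleigh_test(phases)
        z_ref, p_ref = pg.circ_rayleigh(phases)
        assert z == pytest.approx(z_ref, rel=1e-6)
        assert p == pytest.approx(p_ref, rel=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            rayleigh_test(np.empty(0))


class TestUnitCoupling:
    def test_von_mises_unit_recovered(self):
        rng = np.random.default_rng(2)
        phi = phase_of_tone(3.5, 120.0)
        # spikes at times whose phase is von Mises around -0.89
        target = -0.89
        spike_phase = rng.vonmises(target, 2.0, 600)
        cycle = rng.integers(2, 418, 600)
        times = np.unique(
            (cycle + (spike_phase % (2 * np.pi)) / (2 * np.pi)) / 3.5)
        res = unit_coupling(SpikeTrain("u", times), phi, EpochSet(((0, 120),)))
        assert res.significant
        assert wrap_phase(res.circular_mean_rad - target) == pytest.approx(0, abs=0.2)

    def test_too_few_spikes_excluded(self):
        phi = phase_of_tone(3.5, 60.0)
        res = unit_coupling(SpikeTrain("u", np.linspace(1, 50, 9)), phi,
                            EpochSet(((0, 60),)))
        assert res.excluded
        assert not res.significant
        assert np.isnan(res.rayleigh_p)

    def test_uniform_unit_rarely_significant(self):
        phi = phase_of_tone(3.5, 60.0)
        n_sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            times = np.sort(rng.uniform(0, 60, 500))
            times = times[np.diff(times, prepend=-1) > 0]
            res = unit_coupling(SpikeTrain("u", times), phi, EpochSet(((0, 60),)))
            n_sig += res.significant
        assert n_sig <= 10

    def test_circular_mean_estimator_unbiased(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            phases = rng.vonmises(0.7, 2.0, 200)
            errs.append(wrap_phase(circular_mean(phases) - 0.7))
        assert abs(np.mean(errs)) < 0.05

    def test_resultant_length_matches_analytic(self):
        rng = np.random.default_rng(3)
        phases = rng.vonmises(0.0, 2.0, 20000)
        R, _, _ = rayleigh_test(phases)
        assert R == pytest.approx(vonmises_R(2.0), abs=0.02)


def _result(unit_id, rhythm, p, mean=0.0):
    from prr.units import CouplingResult
    return CouplingResult(unit_id, rhythm, 100, 0.5, mean, p)


def _classes(labels):
    from prr.units import UnitClass
    return {u: UnitClass(lab, 0.4, 0.3, 2.0) for u, lab in labels.items()}


class TestPopulationSummary:
    def test_all_units_coupled(self):
        labels = {f"u{i}": ("PYR" if i < 4 else "IN") for i in range(6)}
        results = [_result(u, rh, 0.001)
                   for u in labels for rh in ("prr", "theta")]
        out = population_summary(results, _classes(labels))
        for rh in ("prr", "theta"):
            assert out["fractions"][rh]["PYR"]["fraction_significant"] == 1.0
            assert out["fractions"][rh]["IN"]["fraction_significant"] == 1.0
        assert out["overlap"]["PYR:prr->theta"]["fraction_also"] == 1.0

    def test_disjoint_coupling_zero_overlap(self):
        labels = {f"u{i}": "PYR" for i in range(10)}
        results = []
        for i, u in enumerate(labels):
            results.append(_result(u, "prr", 0.001 if i < 5 else 0.9))
            results.append(_result(u, "theta", 0.9 if i < 5 else 0.001))
        out = population_summary(results, _classes(labels))
        assert out["overlap"]["PYR:prr->theta"]["fraction_also"] == 0.0

    def test_equal_proportions_not_significant(self):
        labels = {f"u{i}": ("PYR" if i < 20 else "IN") for i in range(40)}
        results = [_result(u, "prr", 0.001 if i % 2 else 0.9)
                   for i, u in enumerate(labels)]
        out = population_summary(results, _classes(labels))
        assert out["chi_square"]["prr"]["p"] > 0.05

    def test_empty_results_rejected(self):
        with pytest.raises(InsufficientDataError):
            population_summary([], {})
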