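"""End-to-end orchestration: simulate (or load) sessions, run every
analysis stage, and emit a machine-readable report.

Group-level comparisons follow the standard decision tree: Shapiro-Wilk
normality gate, then a paired/unpaired t-test for normal data or a
Wilcoxon signed-rank / Mann-Whitney U test otherwise, two-tailed, with a
Bonferroni-adjusted critical p when several comparisons are made. The
unit of analysis is the session (animal) for LFP metrics and the unit for
spike metrics.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import __version__
from .core import (
    EpochSet,
    Signal,
    analytic_phase,
    bandpass,
    edge_trimmed_epochs,
    zscore,
)
from .pac import band_modulation_index, comodulogram, extract_theta_epochs, \
    pac_in_theta_epochs, preferred_coupling_phase
from .phase_phase import rnm_surrogate
from .spectral import BANDS, band_peak, coherence, multitaper_psd, normalize_1f
from .synth import SessionConfig, generate_session
from .units import classify_unit, firing_rate, population_summary, unit_coupling

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline", "analyse_session", "group_compare"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Band definitions, window lengths and stage parameters."""

    bands: dict = field(default_factory=lambda: dict(BANDS))
    psd_chunk_s: float = 5.0
    psd_bandwidth_hz: float = 1.0
    pac_window_s: float = 4.0
    comod_phase_freqs: tuple = tuple(np.arange(2.0, 10.5, 1.0))
    comod_amp_freqs: tuple = tuple(np.arange(30.0, 151.0, 5.0))
    m_max: int = 25
    rnm_segments: int = 25
    rnm_segment_len_s: float = 10.0
    edge_trim_s: float = 1.0
    min_epoch_s: float = 2.0
    min_spikes: int = 10
    rhythms: tuple = ("prr", "theta", "respiration")

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name} must satisfy 0 < low < high")


def group_compare(a: np.ndarray, b: np.ndarray, paired: bool = False,
                  alpha: float = 0.05, n_comparisons: int = 1) -> dict:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Normal data (both groups, or the paired differences) go to a t-test;
    otherwise to Wilcoxon's signed-rank (paired) or Mann-Whitney U test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("paired comparison needs equal-length groups")
    if paired:
        diffs = a - b
        normal = a.size >= 3 and stats.shapiro(diffs).pvalue > 0.05
        if normal:
            test, (stat, p) = "paired t-test", stats.ttest_rel(a, b)
        else:
            test, (stat, p) = "wilcoxon", stats.wilcoxon(a, b)
    else:
        normal = (a.size >= 3 and b.size >= 3
                  and stats.shapiro(a).pvalue > 0.05
                  and stats.shapiro(b).pvalue > 0.05)
        if normal:
            test, (stat, p) = "unpaired t-test", stats.ttest_ind(a, b)
        else:
            test, (stat, p) = "mann-whitney", stats.mannwhitneyu(
                a, b, alternative="two-sided")
    p_critical = alpha / n_comparisons
    return {
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "p_critical": p_critical,
        "significant": bool(p < p_critical),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def analyse_session(
    lfp: Signal,
    respiration: Signal | None,
    immobility: EpochSet,
    spike_trains,
    config: AnalysisConfig,
    seed: int = 0,
) -> dict:
    """Run every analysis stage on one session and return a result dict."""
    lfp = zscore(lfp)
    epochs = edge_trimmed_epochs(immobility, lfp.duration, config.edge_trim_s)
    epochs = epochs.filter_min_length(config.min_epoch_s)
    report: dict = {"stages": {}}

    # --- spectra -----------------------------------------------------------
    psd = normalize_1f(multitaper_psd(
        lfp, epochs, config.psd_chunk_s, config.psd_bandwidth_hz))
    peaks = {name: band_peak(psd, band)._asdict()
             for name, band in config.bands.items()}
    spec_stage: dict = {"band_peaks": peaks, "n_chunks": psd.n_chunks}
    if respiration is not None:
        resp_psd = normalize_1f(multitaper_psd(
            zscore(respiration), epochs, config.psd_chunk_s,
            config.psd_bandwidth_hz))
        spec_stage["respiration_peak"] = band_peak(
            resp_psd, config.bands["prr"])._asdict()
        _, (peak_coh, peak_coh_freq) = coherence(lfp, respiration, epochs)
        spec_stage["coherence_peak"] = {
            "coherence": peak_coh, "freq_hz": peak_coh_freq}
    else:
        logger.info("respiration trace absent: coherence stage skipped")
        spec_stage["coherence_peak"] = None
    report["stages"]["spectral"] = spec_stage

    # --- phase series shared by later stages -------------------------------
    prr_band = config.bands["prr"]
    theta_band = config.bands["theta"]
    phi_prr = analytic_phase(bandpass(lfp, *prr_band), prr_band)
    phi_theta = analytic_phase(bandpass(lfp, *theta_band), theta_band)

    # --- n:m phase-phase coupling ------------------------------------------
    profile = rnm_surrogate(
        phi_theta, phi_prr, epochs, m_max=config.m_max,
        n_segments=config.rnm_segments,
        segment_len_s=config.rnm_segment_len_s, seed=seed,
    )
    report["stages"]["phase_phase"] = {
        "m_values": profile.m_values.tolist(),
        "R": profile.R.tolist(),
        "R_surrogate": profile.R_surrogate.tolist(),
        "m_star": profile.m_star,
    }

    # --- phase-amplitude coupling ------------------------------------------
    comod = comodulogram(
        lfp, epochs, window_s=config.pac_window_s,
        phase_freqs_hz=np.asarray(config.comod_phase_freqs),
        amp_freqs_hz=np.asarray(config.comod_amp_freqs),
    )
    mi_prr, dist = band_modulation_index(
        lfp, epochs, prr_band, config.bands["high_gamma"], config.pac_window_s)
    mi_theta, _ = band_modulation_index(
        lfp, epochs, theta_band, config.bands["high_gamma"], config.pac_window_s)
    pref = preferred_coupling_phase(dist)
    pac_stage = {
        "comodulogram_argmax": comod.argmax(),
        "mi_prr": mi_prr,
        "mi_theta": mi_theta,
        "preferred_phase_rad": pref.phase_rad if pref.defined else None,
    }
    try:
        theta_epochs = extract_theta_epochs(lfp).intersect(epochs)
        theta_epochs = EpochSet(tuple(theta_epochs))
        _, ratio = pac_in_theta_epochs(
            lfp, theta_epochs,
            window_s=config.pac_window_s,
            phase_freqs_hz=np.asarray(config.comod_phase_freqs),
            amp_freqs_hz=np.asarray(config.comod_amp_freqs),
        )
        pac_stage["theta_epoch_fraction"] = (
            theta_epochs.total_duration / lfp.duration)
        pac_stage["theta_restricted"] = ratio
    except ValueError as exc:  # includes InsufficientDataError
        logger.info("theta-restricted PAC skipped: %s", exc)
        pac_stage["theta_restricted"] = None
    report["stages"]["pac"] = pac_stage

    # --- single units ------------------------------------------------------
    if spike_trains:
        rhythm_phase = {"prr": phi_prr, "theta": phi_theta}
        if respiration is not None:
            resp_filt = bandpass(zscore(respiration), 1.0, 10.0)
            rhythm_phase["respiration"] = analytic_phase(resp_filt, (1.0, 10.0))
        classes = {}
        rates = {}
        results = []
        for train in spike_trains:
            rate = firing_rate(train, epochs)
            rates[train.unit_id] = rate
            wf = train.waveform if train.waveform is not None else np.empty(0)
            classes[train.unit_id] = classify_unit(wf, train.waveform_fs, rate)
            for rhythm in config.rhythms:
                if rhythm not in rhythm_phase:
                    continue
                results.append(unit_coupling(
                    train, rhythm_phase[rhythm], epochs, rhythm,
                    config.min_spikes))
        summary = population_summary(results, classes)
        pyr_rates = [rates[u] for u, c in classes.items() if c.label == "PYR"]
        in_rates = [rates[u] for u, c in classes.items() if c.label == "IN"]
        rate_comparison = None
        if len(pyr_rates) >= 3 and len(in_rates) >= 3:
            rate_comparison = group_compare(np.array(in_rates), np.array(pyr_rates))
        report["stages"]["units"] = {
            "classes": {u: asdict(c) for u, c in classes.items()},
            "rates_hz": rates,
            "coupling": [asdict(r) | {"significant": r.significant}
                         for r in results],
            "population": summary,
            "rate_comparison_in_vs_pyr": rate_comparison,
        }
    else:
        report["stages"]["units"] = None
    return report


def run_pipeline(
    config: AnalysisConfig | None = None,
    session_config: SessionConfig | None = None,
    seeds: tuple[int, ...] = (0,),
    session_dirs: tuple[str, ...] = (),
    out_path: str | Path | None = None,
) -> dict:
    """Simulate (or load) one or more sessions, analyse each, and bundle
    per-session reports with group-level statistics."""
    from .io import read_session  # local import: io depends on units

    config = config or AnalysisConfig()
    sessions = []
    if session_dirs:
        for d in session_dirs:
            raw = read_session(d)
            sessions.append((Path(d).name, raw["lfp"], raw["respiration"],
                             raw["immobility"], raw["spike_trains"]))
    else:
        session_config = session_config or SessionConfig()
        for s in seeds:
            syn = generate_session(session_config, seed=s)
            sessions.append((f"synthetic-{s}", syn.lfp, syn.respiration,
                             syn.immobility, list(syn.spike_trains)))

    per_session = {}
    for name, lfp, resp, imm, trains in sessions:
        per_session[name] = analyse_session(
            lfp, resp, imm, trains, config,
            seed=zlib.crc32(name.encode()) % (2**31),
        )

    bundle: dict = {
        "version": __version__,
        "config": {
            "bands": config.bands,
            "pac_window_s": config.pac_window_s,
            "psd_chunk_s": config.psd_chunk_s,
            "m_max": config.m_max,
            "edge_trim_s": config.edge_trim_s,
            "min_epoch_s": config.min_epoch_s,
            "min_spikes": config.min_spikes,
        },
        "sessions": per_session,
    }

    if len(per_session) >= 3:
        reports = list(per_session.values())
        m_values = np.array(reports[0]["stages"]["phase_phase"]["m_values"])
        R = np.array([r["stages"]["phase_phase"]["R"] for r in reports])
        Rs = np.array([r["stages"]["phase_phase"]["R_surrogate"] for r in reports])
        m_star = int(m_values[int(np.argmax(R.mean(axis=0)))])
        col = int(np.flatnonzero(m_values == m_star)[0])
        bundle["group"] = {
            "rnm_vs_surrogate": group_compare(R[:, col], Rs[:, col], paired=True)
            | {"m_star": m_star},
            "mi_prr_vs_theta": group_compare(
                np.array([r["stages"]["pac"]["mi_prr"] for r in reports]),
                np.array([r["stages"]["pac"]["mi_theta"] for r in reports]),
                paired=True,
            ),
        }

    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(bundle, fh, indent=1, default=_json_default)
    return bundle


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
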