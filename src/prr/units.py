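"""Single-unit analyses: waveform-based cell-type classification, firing
rates, and spike-phase entrainment to the slow respiration-locked rhythm,
theta, and nasal respiration.

Putative GABAergic interneurons (IN) are separated from putative pyramidal
cells (PYR) by two waveform features of the mean extracellular spike:

* half-duration — width of the trough at half its depth (ms),
* trough-to-peak time — trough to the first subsequent local maximum (ms).

Narrow, fast waveforms (both features below threshold) are labelled IN.
Entrainment of a unit by a rhythm is quantified by the mean resultant
length and circular mean of its spike phases and tested with Rayleigh's
test of circular uniformity; units contributing fewer than 10 spikes inside
the analysis epochs are excluded rather than tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .circular import circular_mean, rayleigh_test, resultant_length  # noqa: F401
from .core import (
    N_PHASE_BINS,
    PHASE_BIN_EDGES,
    EpochSet,
    InsufficientDataError,
    PhaseSeries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "UnitClass",
    "CouplingResult",
    "classify_unit",
    "firing_rate",
    "spike_phases",
    "rayleigh_test",
    "unit_coupling",
    "population_summary",
    "IN_TROUGH_TO_PEAK_MS",
    "IN_HALF_DURATION_MS",
]

# Classification thresholds: midpoints between the IN and PYR group means of
# the two waveform features (IN 0.20 / PYR 0.31 ms trough-to-peak; IN 0.25 /
# PYR 0.47 ms half-duration).
IN_TROUGH_TO_PEAK_MS = 0.25
IN_HALF_DURATION_MS = 0.35


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit plus its mean spike waveform."""

    unit_id: str
    spike_times_s: np.ndarray
    waveform: np.ndarray | None = None
    waveform_fs: float = 30000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "spike_times_s", t)
        if self.waveform is not None:
            object.__setattr__(self, "waveform", np.asarray(self.waveform, dtype=float))

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size


@dataclass(frozen=True)
class UnitClass:
    """Waveform classification of one unit."""

    label: str  # "PYR", "IN" or "unclassifiable"
    half_duration_ms: float
    trough_to_peak_ms: float
    mean_rate_hz: float

    @property
    def classifiable(self) -> bool:
        return self.label in ("PYR", "IN")


@dataclass(frozen=True)
class CouplingResult:
    """Circular statistics of one unit's spike phases against one rhythm."""

    unit_id: str
    rhythm: str
    n_spikes: int
    R: float = np.nan
    circular_mean_rad: float = np.nan
    rayleigh_p: float = np.nan
    excluded: bool = False

    @property
    def significant(self) -> bool:
        return (not self.excluded) and np.isfinite(self.rayleigh_p) and self.rayleigh_p < 0.05


def _half_duration_ms(w: np.ndarray, trough: int, fs: float) -> float | None:
    """Width of the trough lobe at half depth, linear-interpolated crossings."""
    level = w[trough] / 2.0
    left = None
    for i in range(trough, 0, -1):
        if w[i - 1] > level >= w[i]:
            frac = (level - w[i]) / (w[i - 1] - w[i])
            left = i - frac
            break
    right = None
    for i in range(trough, w.size - 1):
        if w[i] <= level < w[i + 1]:
            frac = (level - w[i]) / (w[i + 1] - w[i])
            right = i + frac
            break
    if left is None or right is None:
        return None
    return (right - left) / fs * 1000.0


def classify_unit(
    waveform: np.ndarray,
    waveform_fs: float,
    mean_rate_hz: float,
    *,
    t2p_threshold_ms: float = IN_TROUGH_TO_PEAK_MS,
    half_threshold_ms: float = IN_HALF_DURATION_MS,
) -> UnitClass:
    """Classify a unit as putative pyramidal cell or interneuron.

    The trough is the global minimum of the mean waveform; the peak is the
    first local maximum after it. Units whose trough sits at the waveform
    edge, or whose waveform is positive-going, are flagged unclassifiable.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 5:
        return UnitClass("unclassifiable", np.nan, np.nan, mean_rate_hz)
    trough = int(np.argmin(w))
    depth = -w[trough]
    if trough == 0 or trough == w.size - 1 or depth <= 0 or depth < w.max():
        return UnitClass("unclassifiable", np.nan, np.nan, mean_rate_hz)
    half = _half_duration_ms(w, trough, waveform_fs)
    post = w[trough:]
    peaks, _ = sps.find_peaks(post, prominence=0.05 * depth)
    peak_off = int(peaks[0]) if peaks.size else int(np.argmax(post))
    t2p = peak_off / waveform_fs * 1000.0
    if half is None or t2p <= 0:
        return UnitClass("unclassifiable", np.nan, np.nan, mean_rate_hz)
    label = "IN" if (t2p < t2p_threshold_ms and half < half_threshold_ms) else "PYR"
    return UnitClass(label, half, t2p, mean_rate_hz)


def firing_rate(train: SpikeTrain, epochs: EpochSet) -> float:
    """Mean firing rate inside the epochs: spike count / total epoch time."""
    dur = epochs.total_duration
    if dur <= 0:
        raise ValueError("epochs have zero total duration")
    t = train.spike_times_s
    count = sum(
        int(np.searchsorted(t, b, "left") - np.searchsorted(t, a, "left"))
        for a, b in epochs
    )
    return count / dur


def spike_phases(train: SpikeTrain, phase_series: PhaseSeries, epochs: EpochSet) -> np.ndarray:
    """Rhythm phase at each spike time inside the epochs.

    The phase is read at the nearest phase-series sample (no interpolation,
    no resampling across the different acquisition rates). Spikes outside
    the span of the phase series are skipped and counted in the log.
    """
    t = train.spike_times_s
    if t.size == 0 or len(epochs) == 0:
        return np.empty(0)
    in_epoch = np.zeros(t.size, dtype=bool)
    for a, b in epochs:
        in_epoch |= (t >= a) & (t < b)
    t = t[in_epoch]
    idx = np.round((t - phase_series.t0) * phase_series.fs).astype(int)
    valid = (idx >= 0) & (idx < phase_series.n)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning(
            "unit %s: %d spike(s) outside the phase series span skipped",
            train.unit_id, n_skipped,
        )
    return phase_series.phase[idx[valid]]


def unit_coupling(
    train: SpikeTrain,
    rhythm_phase: PhaseSeries,
    epochs: EpochSet,
    rhythm: str = "prr",
    min_spikes: int = 10,
) -> CouplingResult:
    """Spike-phase entrainment of one unit to one rhythm.

    Units with fewer than ``min_spikes`` spikes inside the epochs are
    returned with the ``excluded`` flag set and no statistics populated.
    """
    phases = spike_phases(train, rhythm_phase, epochs)
    n = phases.size
    if n < min_spikes:
        return CouplingResult(train.unit_id, rhythm, n, excluded=True)
    R, _, p = rayleigh_test(phases)
    return CouplingResult(train.unit_id, rhythm, n, R, circular_mean(phases), p)


def population_summary(
    results: list[CouplingResult],
    classes: dict[str, UnitClass] | list[UnitClass],
    alpha: float = 0.05,
) -> dict:
    """Population-level entrainment summary.

    Per cell class and rhythm: the fraction of (non-excluded) units with
    significant Rayleigh tests, a chi-square test of the PYR-vs-IN
    proportion with a Bonferroni-adjusted critical p, pairwise cross-rhythm
    overlap among significant units, and 18-bin histograms of preferred
    phases.
    """
    if not results:
        raise InsufficientDataError("no coupling results supplied")
    if isinstance(classes, list):
        raise TypeError("classes must map unit_id -> UnitClass")

    rhythms = sorted({r.rhythm for r in results})
    labels = ("PYR", "IN")
    by_rhythm: dict[str, dict[str, CouplingResult]] = {
        rh: {r.unit_id: r for r in results if r.rhythm == rh} for rh in rhythms
    }

    def _units(rhythm: str, label: str) -> list[CouplingResult]:
        return [
            r for r in by_rhythm[rhythm].values()
            if not r.excluded and classes[r.unit_id].label == label
        ]

    fractions: dict[str, dict[str, dict]] = {}
    chi2: dict[str, dict] = {}
    n_tests = len(rhythms)
    for rh in rhythms:
        fractions[rh] = {}
        counts = {}
        for lab in labels:
            units = _units(rh, lab)
            n_sig = sum(r.significant for r in units)
            fractions[rh][lab] = {
                "n_units": len(units),
                "n_significant": n_sig,
                "fraction_significant": n_sig / len(units) if units else np.nan,
            }
            counts[lab] = (n_sig, len(units) - n_sig)
        table = np.array([counts["PYR"], counts["IN"]])
        if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
            stat, p, _, _ = stats.chi2_contingency(table)
            chi2[rh] = {"chi2": float(stat), "p": float(p)}
        else:
            chi2[rh] = {"chi2": np.nan, "p": np.nan}
    p_critical = alpha / n_tests if n_tests else alpha

    overlap: dict[str, dict] = {}
    for rh_a in rhythms:
        for rh_b in rhythms:
            if rh_a == rh_b:
                continue
            for lab in labels:
                sig_a = {r.unit_id for r in _units(rh_a, lab) if r.significant}
                sig_b = {r.unit_id for r in _units(rh_b, lab) if r.significant}
                key = f"{lab}:{rh_a}->{rh_b}"
                overlap[key] = {
                    "n": len(sig_a),
                    "fraction_also": len(sig_a & sig_b) / len(sig_a) if sig_a else np.nan,
                }

    phase_hists: dict[str, dict[str, list[int]]] = {}
    for rh in rhythms:
        phase_hists[rh] = {}
        for lab in labels:
            means = [r.circular_mean_rad for r in _units(rh, lab) if r.significant]
            hist, _ = np.histogram(means, bins=PHASE_BIN_EDGES)
            phase_hists[rh][lab] = hist.tolist()

    return {
        "rhythms": rhythms,
        "fractions": fractions,
        "chi_square": chi2,
        "p_critical": p_critical,
        "overlap": overlap,
        "preferred_phase_histograms": phase_hists,
        "n_phase_bins": N_PHASE_BINS,
    }
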