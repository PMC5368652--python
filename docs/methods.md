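# Methods

This note documents the models and numerical choices behind the package:
what the synthetic generator emulates, how each analysis stage is defined,
which parameters matter, and what the passing tests do and do not show
about real recordings.

## Signal conventions

All traces are uniformly sampled; the LFP is z-scored per session before
analysis (per-session rather than per-animal standardization; the choice
is recorded in pipeline output). Band-pass filtering is a 2nd-order
Butterworth applied forward and reverse (`sosfiltfilt`), which cancels
the phase response but squares the magnitude response — a tone at the
edge of a passband is attenuated more than a single forward pass would
suggest (e.g. gain ≈ 0.93 at 3.5 Hz in the 1–5 Hz band). Instantaneous
phase and amplitude come from the Hilbert analytic signal, with phase 0
at the oscillation peak and ±π at the troughs; every phase histogram in
the package uses 18 bins of 20° on [−π, π).

Filtering is always applied to the full trace and masked by epochs
afterwards, never per epoch, so short epochs carry no filter-edge
artifacts; analyses additionally discard the first and last second of
each recording, where `filtfilt` pad transients live (they decay below
1e-8 within ~3 s at 500 Hz). Epochs shorter than two slow-rhythm cycles
(2 s) are dropped from coupling analyses — a phase estimate over less
than one cycle is meaningless. Spike times recorded at a different rate
than the LFP are never resampled; a spike reads the phase of the nearest
LFP sample.

## Synthetic sessions

The generator is phenomenological, not biophysical. A session is a
deterministic function of (config, seed) and carries its full parameter
record (`GroundTruth`), so analyses can be tested as parameter-recovery
problems.

* **Respiration**: cycle periods are i.i.d. gamma with mean 1/f₀
  (default f₀ = 3.5 Hz, the regular breathing frequency of immobile
  mice) and coefficient of variation `respiration_cv` (default 0.1);
  phase advances linearly within each cycle and the trace is its cosine,
  inspiration positive. cv = 0 degenerates to a pure tone.
* **LFP** is a sum of four components, in units of the background SD:
  a slow component `prr_amp`·cos(φ_resp + lag) (default amplitude 2);
  a theta component cos(r·φ_slow + ε) locked at an integer cycle ratio
  r (default 2) with per-cycle von Mises phase jitter of concentration
  `theta_lock_kappa` (default 4), linearly interpolated across cycles so
  the jittered phase stays smooth; band-limited gamma noise
  (default 80–100 Hz) whose envelope is 1 + `pac_depth`·cos(φ_slow −
  φ_pref); and 1/f^α Gaussian noise (α = 1.5), normalized to unit
  variance. The sum is z-scored. Setting `theta_lock_kappa` = 0 omits
  the theta component entirely — a locked relation with zero
  concentration is undefined, and this convention makes "all couplings
  off" produce pure 1/f noise.
* **Spike trains** are inhomogeneous Poisson processes with intensity
  ∝ exp(κ·cos(φ(t) − φ_pref)), empirically normalized to the target mean
  rate and thinned by a 2 ms absolute refractory period (the intensity
  is pre-compensated for the expected refractory loss, keeping realized
  rates within a few percent of target). Default rates are 1.7 Hz for
  pyramidal cells and 9.4 Hz for interneurons; default preferred phases
  −0.89 and +1.34 rad on the slow rhythm; default entrained fractions
  0.26 and 0.58 of each class.
* **Waveforms** are biphasic templates (Gaussian trough plus a smaller
  positive peak) sampled at 30 kHz on [−1, +2] ms. A damped fixed-point
  calibration adjusts the two shape parameters until the *measured*
  features equal the requested ones to within one sample: half-duration
  0.47 ms / trough-to-peak 0.31 ms for pyramidal templates, 0.25 / 0.20
  ms for interneurons.
* **Immobility** epochs tile the session in 30 s blocks at the requested
  coverage fraction (1.0 → a single full-session epoch).

What the generator does **not** emulate: non-sinusoidal waveform shape
of real slow rhythms, movement and chewing artifacts, non-stationary
breathing frequency drifts, electrode drift, bursting spike statistics,
and volume conduction. Passing recovery tests therefore show that the
analysis chain is correct and well calibrated, not that it is robust to
every pathology of in vivo data.

## Spectra

PSDs are multitaper estimates on disjoint 5 s chunks cut within epochs
(chunks never span an epoch boundary), averaged across chunks. A spectral
bandwidth of 1 Hz on 5 s chunks maps to time-half-bandwidth NW = 2.5 and
⌊2·NW⌋ − 1 = 4 DPSS tapers. Frequency normalization multiplies power by
frequency to flatten the 1/f background before bands are compared; band
peaks are argmaxima of the normalized spectrum (ties break toward the
lower frequency), and both raw and normalized values are available.
Note the effective peak resolution is the taper half-bandwidth (±0.5 Hz),
not the FFT grid spacing: a pure tone smears into a ~±0.4 Hz plateau.

Coherence is Welch magnitude-squared coherence with 0.5·fs-sample Hann
windows at 50% overlap, zero-padded to 10·fs points; auto- and
cross-spectra are pooled across epoch segments weighted by window count.
The peak is reported within 1–10 Hz.

## n:m phase–phase coupling

R_m = |⟨exp i(φ_θ − m·φ_slow)⟩| for m = 1..25, averaged over 25 random
10 s segments drawn uniformly (with replacement) over all positions
where a full segment fits inside one epoch; segment placement is seeded.
Surrogates circularly shift the slow-phase series by a uniform random
5–10 s offset — circular rather than truncating, which preserves the
sample count — and repeat the identical computation with the same
segment placement, giving one matched surrogate per session (an
`n_surrogates` parameter allows distribution-based extensions). Group
inference is a paired two-tailed t-test of real vs surrogate R at the m
maximizing the group-mean real profile; identical vectors return p = 1
rather than NaN.

## Phase–amplitude coupling

The modulation index is D_KL(P‖U)/log N where P is the normalized mean
envelope per phase bin and U uniform; empty phase bins carry zero mass
(x·log x → 0), keeping the divergence finite. MI is exactly 0 for a
phase-constant envelope and exactly 1 for a single-bin point mass. The
comodulogram scans slow bands centered 2–10 Hz (1 Hz bandwidth, 1 Hz
steps) against fast bands centered 30–150 Hz (10 Hz bandwidth, 1 Hz
steps), computing MI in non-overlapping 4 s windows inside the epochs
and averaging window MIs (pooling distributions before one MI is
available as an option). Headline single-band MIs use the full 1–5 Hz
filter for the slow phase and the 80–100 Hz envelope. The preferred
coupling phase is the circular mean of bin centers weighted by P,
flagged undefined when the weighted resultant almost vanishes.

Theta-rich epochs: the theta-filtered trace's rms in 0.5 s windows at
50% overlap (≥ 3 theta cycles per window) is thresholded at its mean
plus two SDs; supra-threshold windows merge when closer than one window.
On stationary 1/f noise this marks ~5–6% of time (the threshold sits in
the right tail of the rms distribution, and 0.5 s windows at 0.25 s hop
double the coverage of isolated detections); with realistic theta bursts
the bursts inflate the threshold and total detections fall below 2% of
the recording. If no 4 s PAC window fits inside the detected epochs, the
window shrinks to the longest epoch with a logged warning.

## Single units

Classification measures the mean waveform's trough width at half depth
and the time from trough to the first subsequent local maximum
(prominence ≥ 5% of trough depth, falling back to the post-trough
argmax); a unit is a putative interneuron when trough-to-peak < 0.25 ms
*and* half-duration < 0.35 ms — midpoints between the two classes'
reported feature means — and a putative pyramidal cell otherwise.
Positive-going waveforms or troughs at the waveform edge are flagged
unclassifiable. Thresholds are configurable.

Spike-phase coupling uses Rayleigh's test with the closed-form
approximation p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)); units with
fewer than 10 spikes inside the epochs are excluded, not tested. For
respiration coupling the respiration trace is band-passed 1–10 Hz before
phase extraction. Population summaries report per-class entrained
fractions, χ² tests of class differences with Bonferroni-adjusted
critical p, pairwise cross-rhythm overlap among significant units, and
18-bin histograms of preferred phases.

A caveat worth knowing: the Hilbert phase of an irregular rhythm has
slightly non-uniform dwell time, so a unit firing uniformly *in time*
has non-uniform spike *phases*; with enough spikes (thousands) the
Rayleigh test resolves this occupancy bias as significant locking with
small R (~0.05–0.1). Interpret significance jointly with R, and prefer
per-class recovery statements at matched spike counts.

## Pipeline statistics

Two-group comparisons pass a Shapiro–Wilk normality gate and route to a
(paired/unpaired) two-tailed t-test or to Wilcoxon's signed-rank /
Mann–Whitney U; multiple comparisons Bonferroni-adjust the critical p.
Per-animal averages precede group statistics for LFP metrics; units are
the unit of analysis for spike metrics. Every number in the report
bundle is reproducible from (inputs, config, seed).

## Problem sizes

Defaults used by the shipped tests and the acceptance script: sessions
of 60–300 s at 1 kHz, comodulograms on reduced grids where the full
9 × 121 scan is not the point, 25 × 10 s segments for R profiles,
600 s traces for theta-epoch calibration, and 2000 replicates for
Rayleigh type-I calibration. These sizes give the statistical power the
assertions need while keeping a full run in the tens of seconds on one
core; all of them scale up by argument.
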