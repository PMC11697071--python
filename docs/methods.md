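# Methods

This note documents the models, parameter choices, and numerical decisions
behind `somnopac`, and what the synthetic-data validation does and does not
establish about real recordings.

## Signal model and preprocessing

Recordings are multi-channel voltage series (EEG1, EEG2, EMG) at a common
sampling rate, nominally 400 Hz, with a 10-s scoring epoch. Conditioning is
a zero-phase (forward–backward) Butterworth chain: 0.5 Hz high-pass of
order 3, 250 Hz low-pass of order 4, and order-4 band-stops at
59.5–60.5 Hz and 119.5–120.5 Hz for power-line contamination and its first
harmonic. Forward–backward application doubles the effective order and
cancels phase distortion; attenuation at the stop-band centers exceeds
20 dB while 50 Hz and 70 Hz pass within 1 dB (verified in the test suite).

At 400 Hz the Nyquist frequency is 200 Hz, so a 250 Hz low-pass corner is
unreachable; the corner is clamped to 0.99 × Nyquist with a warning. The
low-pass is therefore effectively inactive at this rate, which is the
behavior the nominal settings imply.

Because coupling and distribution statistics are duration-dependent,
per-state data are standardized: maximal same-state runs are exported in
temporal order, concatenated, and trimmed from the tail to fixed lengths —
wake 15,000 s, NREM 10,000 s, REM 2,000 s by default. Too little data
raises a typed shortfall error naming available vs required seconds; the
cohort pipeline excludes that subject/state with a logged reason rather
than shortening the window. Filtering happens after concatenation; analysis
windows spanning concatenation seams are kept (the seams are cross-faded in
synthetic data and a 1-s Welch window sees at most one seam; an option to
drop seam-spanning windows would be a straightforward extension).

## Spectral estimation

PSDs use Welch's method with a 1-s Hann window and 25% overlap (overlap
read as a fraction of the window length), i.e. 1 Hz resolution. Band powers
are rectangle-rule integrals over half-open bands [lo, hi). Two presets
exist because two band tables circulate for this kind of data: the default
`figure` preset (delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–50 Hz) and a `methods` preset (delta from 0.5 Hz, gamma to 200 Hz).
The preset is always selected explicitly — the delta lower edge and the
gamma upper edge are never silently mixed. Total Welch power matches the
signal variance within 2% on white noise at every standardized length, and
a sinusoid of amplitude A integrates to A²/2 within 5%.

Distribution-level comparisons of PSD curves use the two-sample
Kolmogorov–Smirnov test on per-frequency density values.

## Phase-amplitude coupling

For a phase band and an amplitude band, the signal is band-passed
(zero-phase Butterworth, order 3) and the analytic signal taken; φ(n) is
its angle in the phase band and f_a(n) its magnitude in the amplitude band.
The first and last 2 s are discarded before any statistic (filter and
Hilbert edge transients). Two modulation indices are computed from the same
mean vector z = (1/N) Σ f_a(n) e^{iφ(n)}:

* raw MI = |z| (mean vector length, envelope units), with the preferred
  coupling phase arg z;
* normalized MI = |z| / (√N · RMS(f_a)), unitless, bounded above by 1/√N
  with equality iff the phase is constant.

The raw index is homogeneous of degree 1 in the envelope and the normalized
index of degree 0, so the pair distinguishes coupling strength from
oscillatory power. Both are computed exactly as written; note that some
descriptive conventions in the literature read *smaller* MI as stronger
coupling — under both formulas here, larger MI means stronger coupling, and
all tests and significance calls use that direction.

Comodulograms default to phase 3–10 Hz and amplitude 50–120 Hz in 1-Hz
steps (fine enough to localize a peak to single-hertz granularity). The
phase bandwidth is 2 Hz; the amplitude bandwidth is max(10 Hz, 2·f_p), wide
enough to admit the modulation sidebands at f_p — an amplitude band
narrower than 2·f_p cannot represent envelope fluctuations at the phase
frequency, which silently destroys real coupling. Ties in the peak cell go
to the lowest phase frequency, then the lowest amplitude frequency.

### Surrogate significance

The null hypothesis is "no phase–envelope alignment". The default surrogate
circularly time-shifts the envelope against the phase by a uniformly random
offset of at least 1 s: both marginals and the envelope autocorrelation are
preserved exactly, only the alignment is destroyed. A block-shuffle and a
full shuffle are also provided; the full shuffle destroys the envelope's
autocorrelation and therefore anti-conservatively inflates significance on
autocorrelated data — it exists for comparison, not as the default.
Empirical p-values use the add-one rule p = (1 + #{null ≥ observed}) /
(n_surrogates + 1), so p ∈ [1/(n+1), 1] and a test with 200 surrogates
rejects at α = 0.05 with probability 10/201 ≈ 0.0498 under exchangeability.
Measured type-I error under zero injected coupling sits inside the 95%
binomial interval around 0.05 (200 replicates, see the acceptance checks).
Multiple cells of a comodulogram are corrected with the Holm step-down
procedure.

## Sleep scoring and architecture

Scoring is a transparent three-rule decision tree over per-epoch features
(EEG RMS, delta-band fraction of 0.5–50 Hz power, theta/delta ratio with
theta read as 4–9 Hz, EMG RMS):

1. EMG RMS above the wake cut → WAKE (precedence: muscle tone trumps EEG);
2. else delta fraction above its cut → NREM;
3. else theta/delta above its cut with EEG RMS below a voltage cut → REM;
4. else NREM (the majority sleep state, a deterministic fallback).

The defaults (wake cut 18 µV, delta fraction 0.5, theta/delta 1.5, EEG RMS
80 µV) are calibrated on the synthetic presets and recover generator
ground truth at ≥ 90% epoch accuracy (in practice ≈ 100% under default
presets — the synthetic states are cleanly separated; see limitations). The
tree is a reproducible stand-in for manual scoring, chosen for testability,
not fidelity to a human rater; no minimum-bout smoothing is applied by
default (an optional 2-epoch smoother exists).

Bouts are maximal same-state runs. Architecture summaries split the
recording into alternating light/dark blocks (12 h by default, first block
light, recording assumed to start at light onset — the onset clock time
must come from the experiment). Per block and state: percent time, mean
bout duration, the 3×3 from→to transition count matrix, and arousals
(NREM→WAKE, REM→WAKE). Because "arousals per sleep cycle" has no standard
definition, arousal counts are reported both raw per block and per hour
spent in the origin state; comparisons use per-block counts by default. A
bout spanning a block boundary is attributed to the block containing its
onset (deterministic and order-preserving); transitions are attributed to
the block containing the origin epoch.

## Group statistics

Each metric passes a normality gate: Shapiro–Wilk and Anderson–Darling at
the 5% level in every group. Only if neither test rejects anywhere is the
metric treated as parametric (disagreement between the two tests falls to
the nonparametric branch — the conservative choice); groups with n < 3
are nonparametric by fiat. Parametric metrics use the Tukey–Kramer HSD;
nonparametric metrics use the Steel–Dwass (Dwass–Steel–Critchlow–Fligner)
all-pairs rank procedure, implemented as the tie-corrected standardized
Mann–Whitney statistic referred to the studentized range distribution
(for two groups this collapses to the two-sided normal Mann–Whitney
approximation, which the tests verify). Family-wise error across the
report's metric families uses Holm. The end-to-end pipeline is
deterministic: a fixed config and seed reproduce byte-identical CSVs.

## The synthetic generator

The generator exists so that every downstream stage has ground truth. Per
state it emulates: a first-order Markov hypnogram in 10-s epochs (separate
light- and dark-phase transition matrices, wake-dominant in the dark);
EEG as a sum of band-limited Gaussian oscillatory components plus a 1/f^β
pink background (β = 1 by default), each scaled to an exact RMS; and EMG as
broadband noise with state-dependent RMS (wake 30, NREM 10, REM 2 µV).
State presets encode the conventional scoring criteria numerically — e.g.
NREM delta RMS 45 µV against a wake pink background of 15 µV; these are
presets chosen for clear state separation, not measured claims about any
animal. Segments are generated per bout and joined with a 0.5-s cosine
cross-fade to avoid spectral splatter at state boundaries. Voltage units
are nominal µV (absolute calibration of amplified recordings is
rig-specific and intentionally not modeled).

Coupling is injected as amplitude modulation: a slow carrier at f_p
(default 8 Hz) and a fast component at f_a (default 100 Hz) whose
instantaneous amplitude follows

    env(t) = A · [(1 − χ) + χ · (1 + cos θ(t)) / 2],

θ(t) the carrier phase, so χ = 0 gives a flat envelope and χ = 1 a full
swing peaking at the carrier's cosine peak; A is normalized so the fast
component's RMS is χ-independent. The carrier's instantaneous frequency
wanders slowly (low-passed Gaussian wander, RMS 0.5 Hz by default) rather
than staying a pure sinusoid: real theta is not strictly periodic, and a
strictly periodic carrier would defeat time-shift surrogates entirely (a
circular shift of a periodic envelope merely rotates the mean vector
without changing its length). Both MI statistics increase strictly in χ on
a fixed-seed grid, which is what makes χ a usable ground-truth dial.

Seeds: every random component derives its own `numpy.random.SeedSequence`
from the master seed via a fixed spawn key (group, subject, channel, bout,
component), so cohorts are reproducible element-wise, subjects and channels
never share noise streams, and changing χ alone leaves all noise untouched.

### What the generator does not emulate

No artifacts (electrode pops, movement, chewing), no circadian drift beyond
the light/dark block structure, no inter-subject variability in spectral
profiles beyond the seeded noise, no ambiguous transitional epochs, and no
biophysical neural-mass dynamics. Consequently, the scorer's near-perfect
accuracy on synthetic data shows the decision tree implements its rules
correctly and that the rules match the generator's encoding of the scoring
criteria — not that it matches a human rater on real mouse EEG, where
thresholds would need per-lab calibration and accuracy would be lower.
Likewise, surrogate calibration on synthetic signals validates the
procedure's logic, not robustness to every real-world nonstationarity.

## Problem sizes used in validation

The test suite and acceptance script run on deliberately compact problems:
60-s signals at 400 Hz for MI/surrogate/comodulogram checks, 200 replicates
for type-I calibration, 100,000-epoch hypnograms for Markov closed forms,
0.5–1 h recordings for scorer recovery, and a 2 × 3-subject cohort at 2 h
with reduced standardization targets (1,200/1,200/240 s) and 1-h blocks for
the end-to-end determinism check. These sizes give tight statistical
checks while keeping the whole validation battery fast; all durations and
targets scale to full 24-h cohorts through configuration alone.

## Known limitations

* The rule-based scorer is a stand-in, not a rater emulation; there is no
  artifact-epoch handling.
* EDF support is plain EDF (16-bit) with equal per-channel rates;
  EDF+ annotation channels are skipped with a warning, never written.
* The comodulogram recomputes the band-pass per cell; for very long signals
  this is the dominant cost (it is linear in cells × samples).
* Welch windows spanning concatenation seams are retained (see above).
* The normality gate applies two tests per group without correcting the
  gate itself for multiplicity; this makes the parametric branch harder to
  enter, which is the intended conservative direction.
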