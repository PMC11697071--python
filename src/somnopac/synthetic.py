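"""Synthetic polysomnography cohorts with known ground truth.

The generator emulates the statistical structure a rodent sleep-EEG analysis
assumes: a first-order Markov hypnogram over WAKE/NREM/REM in 10-s epochs,
state-dependent EEG spectra (narrow-band oscillatory components plus 1/f^beta
pink background), state-dependent EMG tone, and — optionally — theta-phase to
gamma-amplitude coupling injected with a controllable strength chi in [0, 1].

Coupling construction
---------------------
The fast component at frequency ``f_a`` is a sinusoid whose instantaneous
amplitude follows the phase theta(t) of an added slow carrier at ``f_p``::

    env(t) = A * [(1 - chi) + chi * (1 + cos(theta(t))) / 2]

so at chi=0 the envelope is flat (no coupling) and at chi=1 it swings from 0
to A, peaking at the cosine peak of the slow rhythm. ``A`` is chosen so the
RMS of the fast component equals the requested ``modulated_rms`` for every
chi. Both mean-vector-length modulation indices respond monotonically to chi,
which is what makes the generator a usable oracle for the coupling analysis.

Seed policy
-----------
Every drawn component gets its own ``numpy.random.SeedSequence`` derived from
the master seed by a fixed spawn key ``(group, subject, channel, bout,
component)``, so cohorts are reproducible element-wise and two subjects (or
channels) never share a noise stream. Because the coupling envelope is
deterministic given the carrier phase, changing chi alone leaves every noise
stream untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .core import (
    STATES,
    Hypnogram,
    Recording,
    ValidationError,
    validate_transition_matrix,
)

__all__ = [
    "StateProfile",
    "PacInjectionSpec",
    "GroupSpec",
    "CohortSpec",
    "default_profiles",
    "default_pac",
    "default_transition_matrix",
    "default_cohort_spec",
    "simulate_hypnogram",
    "synthesize_state_segment",
    "synthesize_recording",
]

#: Duration of the cosine cross-fade applied at state boundaries (s).
CROSSFADE_S = 0.5


@dataclass(frozen=True)
class StateProfile:
    """Spectral recipe for one vigilance state.

    ``band_amplitudes`` lists oscillatory components as
    ``(center_hz, bandwidth_hz, rms_uv)`` triples; each is realized as
    band-limited Gaussian noise scaled to the requested RMS. The pink
    background has power density proportional to ``1/f**pink_noise_exponent``.
    """

    state: str
    band_amplitudes: tuple[tuple[float, float, float], ...]
    pink_noise_rms: float
    pink_noise_exponent: float
    emg_rms: float

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        for c, bw, rms in self.band_amplitudes:
            if c <= 0 or bw <= 0 or rms < 0:
                raise ValidationError(
                    f"bad band component (center={c}, bw={bw}, rms={rms})"
                )
        if self.pink_noise_rms < 0 or self.emg_rms < 0:
            raise ValidationError("RMS values must be non-negative")
        if not 0 <= self.pink_noise_exponent <= 2:
            raise ValidationError("pink-noise exponent must lie in [0, 2]")

    def scaled(self, factor: float) -> "StateProfile":
        """Return a copy with all EEG band RMS values multiplied by ``factor``."""
        bands = tuple((c, bw, rms * factor) for c, bw, rms in self.band_amplitudes)
        return replace(self, band_amplitudes=bands)


@dataclass(frozen=True)
class PacInjectionSpec:
    """Parameters of the injected slow-phase -> fast-amplitude coupling."""

    phase_freq_hz: float = 8.0
    amplitude_freq_hz: float = 100.0
    coupling_strength: float = 0.8
    carrier_rms: float = 15.0
    modulated_rms: float = 5.0
    #: RMS of the slow carrier's instantaneous-frequency wander (Hz). Real
    #: theta is not a pure sinusoid; the wander decorrelates the carrier
    #: phase over a few seconds, which is what lets time-shift surrogates
    #: destroy the coupling they are meant to null out.
    frequency_jitter_hz: float = 0.5

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2
        if not 0 <= self.coupling_strength <= 1:
            raise ValidationError("coupling strength chi must lie in [0, 1]")
        if not self.phase_freq_hz < self.amplitude_freq_hz:
            raise ValidationError("phase frequency must be below amplitude frequency")
        if self.amplitude_freq_hz >= nyq:
            raise ValidationError(
                f"amplitude frequency {self.amplitude_freq_hz} Hz is at or above "
                f"Nyquist ({nyq} Hz)"
            )
        if self.carrier_rms < 0 or self.modulated_rms < 0:
            raise ValidationError("RMS values must be non-negative")


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generator settings: cohort size, profiles, and coupling."""

    n_subjects: int
    profiles: dict[str, StateProfile]
    pac: dict[str, PacInjectionSpec | None]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        missing = set(STATES) - set(self.profiles)
        if missing:
            raise ValidationError(f"missing state profiles: {sorted(missing)}")


@dataclass
class CohortSpec:
    """Full declarative description of a synthetic cohort."""

    groups: dict[str, GroupSpec]
    transition_matrix: np.ndarray
    dark_transition_matrix: np.ndarray | None = None
    epoch_length_s: float = 10.0
    sampling_rate_hz: float = 400.0
    duration_h: float = 24.0
    light_onset_hour: float = 6.0
    block_hours: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = validate_transition_matrix(self.transition_matrix)
        if self.dark_transition_matrix is not None:
            self.dark_transition_matrix = validate_transition_matrix(
                self.dark_transition_matrix
            )
        dur_s = self.duration_h * 3600.0
        n_epochs = dur_s / self.epoch_length_s
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise ValidationError("duration must be divisible by the epoch length")
        for g in self.groups.values():
            for pac in g.pac.values():
                if pac is not None:
                    pac.validate(self.sampling_rate_hz)

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.epoch_length_s))


def default_profiles(
    amplitude_scale: dict[str, float] | None = None,
) -> dict[str, StateProfile]:
    """Presets encoding the conventional scoring criteria numerically.

    Wake: low-amplitude, mixed high-frequency EEG with high EMG tone; NREM:
    high-voltage slow (delta) EEG, low EMG; REM: theta-dominant low-voltage
    EEG with EMG atonia. NREM delta RMS is 3x the wake pink background —
    these values are presets chosen for clear state separation, not measured
    quantities. ``amplitude_scale`` multiplies the EEG band RMS values of the
    named states (used to emulate group differences in oscillatory power).
    """
    profiles = {
        "WAKE": StateProfile(
            state="WAKE",
            band_amplitudes=((10.0, 4.0, 10.0), (25.0, 10.0, 8.0)),
            pink_noise_rms=15.0,
            pink_noise_exponent=1.0,
            emg_rms=30.0,
        ),
        "NREM": StateProfile(
            state="NREM",
            band_amplitudes=((2.0, 3.0, 45.0), (12.0, 2.0, 10.0)),
            pink_noise_rms=20.0,
            pink_noise_exponent=1.0,
            emg_rms=10.0,
        ),
        "REM": StateProfile(
            state="REM",
            band_amplitudes=((7.0, 2.0, 25.0),),
            pink_noise_rms=12.0,
            pink_noise_exponent=1.0,
            emg_rms=2.0,
        ),
    }
    for state, factor in (amplitude_scale or {}).items():
        profiles[state] = profiles[state].scaled(factor)
    return profiles


def default_pac(coupling_strength: float = 0.8) -> dict[str, PacInjectionSpec | None]:
    """Inject 8 Hz -> 100 Hz coupling of the given strength in every state."""
    spec = PacInjectionSpec(coupling_strength=coupling_strength)
    return {s: spec for s in STATES}


def default_transition_matrix() -> np.ndarray:
    """Light-phase transition matrix: sleep-rich, mean bouts of a few minutes."""
    return np.array(
        [
            [0.950, 0.050, 0.000],  # WAKE
            [0.030, 0.950, 0.020],  # NREM
            [0.100, 0.000, 0.900],  # REM
        ]
    )


def default_dark_transition_matrix() -> np.ndarray:
    """Dark-phase matrix: wake-dominant (nocturnal activity)."""
    return np.array(
        [
            [0.980, 0.020, 0.000],
            [0.060, 0.920, 0.020],
            [0.100, 0.000, 0.900],
        ]
    )


def default_cohort_spec(
    n_per_group: int = 5,
    duration_h: float = 24.0,
    seed: int = 0,
    group_settings: dict[str, dict] | None = None,
) -> CohortSpec:
    """Two-group cohort: controls with strong coupling, a 'ko' group with
    weakened coupling and halved NREM delta amplitude (emulating an ablation
    phenotype: less slow-wave power, attenuated theta–gamma coupling)."""
    if group_settings is None:
        group_settings = {
            "control": {"coupling_strength": 0.8},
            "ko": {"coupling_strength": 0.2, "amplitude_scale": {"NREM": 0.5}},
        }
    groups = {}
    for name, cfg in group_settings.items():
        groups[name] = GroupSpec(
            n_subjects=cfg.get("n_subjects", n_per_group),
            profiles=default_profiles(cfg.get("amplitude_scale")),
            pac=default_pac(cfg.get("coupling_strength", 0.8)),
        )
    return CohortSpec(
        groups=groups,
        transition_matrix=default_transition_matrix(),
        dark_transition_matrix=default_dark_transition_matrix(),
        duration_h=duration_h,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# seed plumbing


def _child(ss: np.random.SeedSequence, *key: int) -> np.random.SeedSequence:
    """Derive a child SeedSequence by extending the spawn key (stateless)."""
    return np.random.SeedSequence(ss.entropy, spawn_key=ss.spawn_key + tuple(key))


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# hypnogram simulation


def simulate_hypnogram(
    transition_matrix: np.ndarray,
    n_epochs: int,
    seed,
    initial_state: str = "WAKE",
    epoch_length_s: float = 10.0,
) -> Hypnogram:
    """Simulate a first-order Markov hypnogram over WAKE/NREM/REM.

    The chain starts in ``initial_state`` and steps once per epoch using the
    row-stochastic ``transition_matrix`` (rows/columns in :data:`STATES`
    order). Reproducible for a fixed seed.
    """
    m = validate_transition_matrix(transition_matrix)
    if n_epochs < 1:
        raise ValidationError("n_epochs must be >= 1")
    if initial_state not in STATES:
        raise ValidationError(f"unknown initial state {initial_state!r}")
    rng = np.random.default_rng(_as_seedseq(seed))
    cum = np.cumsum(m, axis=1)
    u = rng.random(n_epochs - 1)
    codes = np.empty(n_epochs, dtype=np.int64)
    codes[0] = STATES.index(initial_state)
    for i in range(1, n_epochs):
        codes[i] = np.searchsorted(cum[codes[i - 1]], u[i - 1], side="right")
    labels = np.array(STATES, dtype="<U4")[np.minimum(codes, 2)]
    return Hypnogram(states=labels, epoch_length_s=epoch_length_s)


# ---------------------------------------------------------------------------
# signal synthesis


def _band_noise(
    n: int, rate: float, center: float, bandwidth: float, rms: float, rng
) -> np.ndarray:
    """Band-limited Gaussian noise scaled to an exact RMS."""
    nyq = rate / 2
    lo = max(center - bandwidth / 2, 1e-3)
    hi = min(center + bandwidth / 2, 0.99 * nyq)
    if center >= nyq:
        raise ValidationError(f"component frequency {center} Hz is at or above Nyquist")
    x = rng.standard_normal(n)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    cur = np.sqrt(np.mean(y**2))
    return y * (rms / cur) if cur > 0 else y


def _pink_noise(n: int, rate: float, beta: float, rms: float, rng) -> np.ndarray:
    """1/f^beta noise via frequency-domain shaping, scaled to an exact RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spectrum = (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    ).astype(complex)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shape, n=n)
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def _pac_components(
    pac: PacInjectionSpec, n: int, rate: float, rng
) -> np.ndarray:
    """Slow carrier plus amplitude-modulated fast component.

    The fast envelope is ``A * [(1 - chi) + chi * (1 + cos(theta)) / 2]``
    where theta is the slow carrier's phase, so envelope maxima coincide with
    the carrier's cosine peaks. ``A`` normalizes the fast component's RMS to
    ``modulated_rms`` independent of chi.
    """
    chi = pac.coupling_strength
    t = np.arange(n) / rate
    phi0 = rng.uniform(-np.pi, np.pi)
    psi0 = rng.uniform(-np.pi, np.pi)
    f_inst = np.full(n, pac.phase_freq_hz)
    if pac.frequency_jitter_hz > 0 and n > 100:
        # slow (<1 Hz) instantaneous-frequency wander of the carrier
        sos = signal.butter(2, min(1.0, 0.4 * rate / 2), btype="lowpass", fs=rate,
                            output="sos")
        wander = signal.sosfiltfilt(sos, rng.standard_normal(n))
        wander *= pac.frequency_jitter_hz / np.sqrt(np.mean(wander**2))
        f_inst = f_inst + wander
    theta = 2 * np.pi * np.cumsum(f_inst) / rate + phi0
    carrier = np.sqrt(2.0) * pac.carrier_rms * np.cos(theta)
    # E[env^2] = A^2 * ((1 - chi/2)^2 + chi^2/8); fast RMS = sqrt(E[env^2]/2)
    norm = np.sqrt((1 - chi / 2) ** 2 + chi**2 / 8)
    amp = pac.modulated_rms * np.sqrt(2.0) / norm
    env = amp * ((1 - chi) + chi * (1 + np.cos(theta)) / 2)
    fast = env * np.cos(2 * np.pi * pac.amplitude_freq_hz * t + psi0)
    return carrier + fast


def synthesize_state_segment(
    profile: StateProfile,
    pac: PacInjectionSpec | None,
    duration_s: float,
    sampling_rate_hz: float,
    seed,
) -> np.ndarray:
    """Synthesize one EEG segment of a single vigilance state.

    Output is the sum of the profile's band-limited oscillatory components,
    the pink background, and (when ``pac`` is given) the coupled
    carrier/modulated pair. Each component draws from its own child seed, so
    varying the coupling strength alone does not perturb the noise streams.
    """
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    nyq = sampling_rate_hz / 2
    n = int(round(duration_s * sampling_rate_hz))
    ss = _as_seedseq(seed)
    out = np.zeros(n)
    for i, (center, bw, rms) in enumerate(profile.band_amplitudes):
        if center >= nyq:
            raise ValidationError(
                f"band center {center} Hz is at or above Nyquist ({nyq} Hz)"
            )
        out += _band_noise(
            n, sampling_rate_hz, center, bw, rms, np.random.default_rng(_child(ss, 0, i))
        )
    if profile.pink_noise_rms > 0:
        out += _pink_noise(
            n,
            sampling_rate_hz,
            profile.pink_noise_exponent,
            profile.pink_noise_rms,
            np.random.default_rng(_child(ss, 1)),
        )
    if pac is not None:
        pac.validate(sampling_rate_hz)
        out += _pac_components(
            pac, n, sampling_rate_hz, np.random.default_rng(_child(ss, 2))
        )
    return out


def _crossfade_concat(segments: list[np.ndarray], fade_n: int) -> np.ndarray:
    """Concatenate segments with a cosine cross-fade of ``fade_n`` samples.

    Each segment must carry ``fade_n`` extra tail samples beyond its nominal
    length; the tail of segment *k* is blended into the head of segment
    *k + 1*. The last tail is discarded.
    """
    if fade_n > 0:
        w_up = 0.5 * (1 - np.cos(np.pi * np.arange(fade_n) / fade_n))
        w_down = 1.0 - w_up
    pieces = []
    prev_tail: np.ndarray | None = None
    for seg in segments:
        body, tail = seg[: seg.size - fade_n], seg[seg.size - fade_n :]
        body = body.copy()
        if prev_tail is not None and fade_n > 0:
            k = min(fade_n, body.size)
            body[:k] = w_down[:k] * prev_tail[:k] + w_up[:k] * body[:k]
        pieces.append(body)
        prev_tail = tail
    return np.concatenate(pieces)


def _simulate_blockwise_hypnogram(spec: CohortSpec, subject_key: tuple[int, int]) -> Hypnogram:
    """Markov hypnogram with a per-block (light/dark) transition matrix."""
    ss = _as_seedseq(spec.seed)
    epochs_per_block = int(round(spec.block_hours * 3600 / spec.epoch_length_s))
    n_total = spec.n_epochs
    matrices = [spec.transition_matrix]
    if spec.dark_transition_matrix is not None:
        matrices.append(spec.dark_transition_matrix)
    labels: list[np.ndarray] = []
    state = "WAKE"
    block = 0
    produced = 0
    while produced < n_total:
        n_block = min(epochs_per_block, n_total - produced)
        m = matrices[block % len(matrices)]
        hyp = simulate_hypnogram(
            m,
            n_block,
            _child(ss, *subject_key, 10_000 + block),
            initial_state=state,
            epoch_length_s=spec.epoch_length_s,
        )
        labels.append(hyp.states)
        state = str(hyp.states[-1])
        produced += n_block
        block += 1
    return Hypnogram(states=np.concatenate(labels), epoch_length_s=spec.epoch_length_s)


def synthesize_recording(
    spec: CohortSpec, group: str, subject_index: int
) -> tuple[Recording, Hypnogram]:
    """Generate one subject's EEG1/EEG2/EMG recording and its true hypnogram.

    EEG segments are generated per state bout and joined with a 0.5-s cosine
    cross-fade at state boundaries; EMG is state-dependent broadband noise
    joined the same way.
    """
    if group not in spec.groups:
        raise ValidationError(f"unknown group {group!r}")
    gspec = spec.groups[group]
    if not 0 <= subject_index < gspec.n_subjects:
        raise ValidationError(
            f"subject index {subject_index} out of range for group {group!r}"
        )
    gi = list(spec.groups).index(group)
    rate = spec.sampling_rate_hz
    ss = _as_seedseq(spec.seed)
    hyp = _simulate_blockwise_hypnogram(spec, (gi, subject_index))

    # bout decomposition of the true hypnogram
    codes = hyp.codes()
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))

    fade_n = int(round(CROSSFADE_S * rate))
    channels = []
    for ch_idx, role in enumerate(("EEG1", "EEG2")):
        segs = []
        for b, (s0, s1) in enumerate(zip(starts, ends)):
            state = STATES[codes[s0]]
            dur = (s1 - s0) * spec.epoch_length_s + fade_n / rate
            segs.append(
                synthesize_state_segment(
                    gspec.profiles[state],
                    gspec.pac.get(state),
                    dur,
                    rate,
                    _child(ss, gi, subject_index, ch_idx, b),
                )
            )
        channels.append(_crossfade_concat(segs, fade_n))
    # EMG: state-dependent broadband noise
    emg_segs = []
    for b, (s0, s1) in enumerate(zip(starts, ends)):
        state = STATES[codes[s0]]
        n = int(round((s1 - s0) * spec.epoch_length_s * rate)) + fade_n
        rng = np.random.default_rng(_child(ss, gi, subject_index, 2, b))
        emg_segs.append(gspec.profiles[state].emg_rms * rng.standard_normal(n))
    channels.append(_crossfade_concat(emg_segs, fade_n))

    rec = Recording(
        data=np.vstack(channels),
        channel_labels=("EEG1", "EEG2", "EMG"),
        sampling_rate_hz=rate,
        subject_id=f"{group}-{subject_index:02d}",
        group=group,
    )
    return rec, hyp
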