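"""Theta–gamma phase-amplitude coupling (PAC) statistics.

Given a slow-band phase series φ(n) and a fast-band amplitude envelope
f_a(n), both of length N, two mean-vector-length modulation indices are
computed:

* the raw (Canolty) form, in envelope units::

      MI = | (1/N) Σ_n f_a(n) · exp(i φ(n)) |

  whose modulus is the mean vector length and whose argument is the
  preferred coupling phase; and

* a power-normalized form, unitless and bounded by 1/√N::

      MI_norm = (1/√N) · | (1/N) Σ f_a e^{iφ} | / sqrt( (1/N) Σ f_a(n)² )

  which divides out the fast oscillation's RMS so that MI differences
  reflect coupling rather than oscillatory power.

Scaling the envelope by k scales the raw MI by k exactly and leaves the
normalized MI unchanged — the pair separates coupling strength from power.
Note these formulas read "higher = stronger coupling"; both are used that
way here.

Significance uses a surrogate null: the envelope is circularly time-shifted
(or shuffled) against the phase to destroy any phase–amplitude alignment
while preserving both marginals, the MI is recomputed per surrogate, and the
empirical p-value uses the add-one rule p = (1 + #{null ≥ observed}) /
(n_surrogates + 1). Comodulograms scan MI over a phase-frequency ×
amplitude-frequency grid (3–10 Hz against 50–120 Hz by default) with
optional per-cell surrogate p-values and Holm correction across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

__all__ = [
    "PhaseAmplitudeSeries",
    "MIResult",
    "SurrogateNull",
    "PhaseHistogram",
    "Comodulogram",
    "extract_phase",
    "extract_amplitude",
    "phase_amplitude_series",
    "mi_canolty",
    "mi_normalized",
    "phase_sorted_amplitude_histogram",
    "surrogate_test",
    "comodulogram",
    "comodulogram_peak",
]

#: Seconds discarded at each end of extracted series (filter transients).
EDGE_TRIM_S = 2.0


@dataclass
class PhaseAmplitudeSeries:
    """Paired phase series and amplitude envelope — the MI operands."""

    phase: np.ndarray
    amplitude: np.ndarray
    sampling_rate_hz: float
    phase_band_hz: tuple[float, float] = (0.0, 0.0)
    amplitude_band_hz: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape or self.phase.ndim != 1:
            raise ValidationError("phase and amplitude must be equal-length 1-D arrays")
        if self.phase.size < 2:
            raise ValidationError("need at least 2 samples")
        if (self.amplitude < 0).any():
            raise ValidationError("amplitude envelope must be non-negative")

    @property
    def n(self) -> int:
        return int(self.phase.size)


@dataclass(frozen=True)
class MIResult:
    """Both modulation indices plus the mean-vector summary."""

    mi_canolty: float
    mi_normalized: float | None
    mean_vector_length: float
    mean_vector_angle: float
    n: int


@dataclass
class SurrogateNull:
    """Randomization null for one observed MI."""

    scheme: str
    n_surrogates: int
    seed: int | None
    observed: float
    null_mi: np.ndarray
    p: float


@dataclass
class PhaseHistogram:
    """Mean envelope per phase bin over a partition of (-π, π]."""

    bin_centers: np.ndarray
    mean_amplitude: np.ndarray
    counts: np.ndarray
    has_empty_bins: bool


@dataclass
class Comodulogram:
    """MI over a (phase frequency × amplitude frequency) grid."""

    phase_freqs_hz: np.ndarray
    amp_freqs_hz: np.ndarray
    mi: np.ndarray  # shape (n_phase, n_amp)
    method: str
    p: np.ndarray | None = None
    significant: np.ndarray | None = None
    holm_alpha: float | None = None
    phase_bandwidth_hz: float = 2.0
    amp_bandwidths_hz: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _analytic(x: np.ndarray) -> np.ndarray:
    """Analytic signal via the frequency-domain transform, padded to a fast
    FFT length and truncated back."""
    from scipy.fft import next_fast_len

    n = x.size
    return sps.hilbert(x, N=next_fast_len(n))[:n]


def _bandpass(x: np.ndarray, rate: float, band: tuple[float, float], order: int = 3):
    lo, hi = band
    nyq = rate / 2
    if not 0 < lo < hi < nyq:
        raise ValidationError(f"band ({lo}, {hi}) Hz must lie inside (0, {nyq:g}) Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= 3 * padlen:
        raise ValidationError(
            f"signal of {x.size} samples is too short for a ({lo}, {hi}) Hz band"
        )
    return sps.sosfiltfilt(sos, x)


def extract_phase(
    samples: np.ndarray, rate: float, band: tuple[float, float], order: int = 3
) -> np.ndarray:
    """Instantaneous phase (radians in (-π, π]) of the band-passed signal.

    Zero-phase Butterworth band-pass, then the analytic-signal angle. The
    caller should discard :data:`EDGE_TRIM_S` at each end before computing
    statistics.
    """
    x = np.asarray(samples, dtype=float)
    phase = np.angle(_analytic(_bandpass(x, rate, band, order)))
    # np.angle returns [-π, π]; fold -π onto +π for the (-π, π] convention
    phase[phase == -np.pi] = np.pi
    return phase


def extract_amplitude(
    samples: np.ndarray, rate: float, band: tuple[float, float], order: int = 3
) -> np.ndarray:
    """Instantaneous amplitude envelope (≥ 0) of the band-passed signal."""
    x = np.asarray(samples, dtype=float)
    return np.abs(_analytic(_bandpass(x, rate, band, order)))


def phase_amplitude_series(
    samples: np.ndarray,
    rate: float,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    edge_trim_s: float = EDGE_TRIM_S,
) -> PhaseAmplitudeSeries:
    """Extract a trimmed phase/envelope pair from one signal."""
    phase = extract_phase(samples, rate, phase_band)
    amp = extract_amplitude(samples, rate, amp_band)
    k = int(round(edge_trim_s * rate))
    if phase.size <= 2 * k + 1:
        raise ValidationError("signal too short after edge trimming")
    sl = slice(k, phase.size - k) if k else slice(None)
    return PhaseAmplitudeSeries(
        phase=phase[sl],
        amplitude=amp[sl],
        sampling_rate_hz=rate,
        phase_band_hz=phase_band,
        amplitude_band_hz=amp_band,
    )


def _mean_vector(series: PhaseAmplitudeSeries) -> complex:
    return complex(np.mean(series.amplitude * np.exp(1j * series.phase)))


def mi_canolty(series: PhaseAmplitudeSeries) -> MIResult:
    """Raw mean-vector-length modulation index (envelope units)."""
    z = _mean_vector(series)
    power = float(np.mean(series.amplitude**2))
    norm = (
        abs(z) / (np.sqrt(series.n) * np.sqrt(power)) if power > 0 else None
    )
    return MIResult(
        mi_canolty=abs(z),
        mi_normalized=norm,
        mean_vector_length=abs(z),
        mean_vector_angle=float(np.angle(z)),
        n=series.n,
    )


def mi_normalized(series: PhaseAmplitudeSeries) -> MIResult:
    """Power-normalized modulation index (unitless, ≤ 1/√N)."""
    if not float(np.sum(series.amplitude**2)) > 0:
        raise ValidationError("normalized MI is undefined for an all-zero envelope")
    return mi_canolty(series)


def _mi_value(series: PhaseAmplitudeSeries, method: str) -> float:
    res = mi_canolty(series) if method == "canolty" else mi_normalized(series)
    if method == "canolty":
        return res.mi_canolty
    if method == "normalized":
        return float(res.mi_normalized)
    raise ValidationError(f"unknown MI method {method!r}")


def phase_sorted_amplitude_histogram(
    series: PhaseAmplitudeSeries, n_bins: int = 18
) -> PhaseHistogram:
    """Mean envelope within each of ``n_bins`` equal phase bins over (-π, π].

    Empty bins report a mean of 0 and are flagged.
    """
    if n_bins < 2:
        raise ValidationError("need at least 2 phase bins")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # bins are half-open (lo, hi]: digitize with right=True on interior edges
    idx = np.digitize(series.phase, edges[1:-1], right=True)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=series.amplitude, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    centers = (edges[:-1] + edges[1:]) / 2
    return PhaseHistogram(
        bin_centers=centers,
        mean_amplitude=means,
        counts=counts,
        has_empty_bins=bool((counts == 0).any()),
    )


def _surrogate_envelopes(
    series: PhaseAmplitudeSeries,
    scheme: str,
    n_surrogates: int,
    rng: np.random.Generator,
):
    """Yield randomized envelopes that break phase–amplitude alignment."""
    n = series.n
    amp = series.amplitude
    rate = series.sampling_rate_hz
    if scheme == "circular_shift":
        min_shift = min(int(round(rate)), n // 4)  # at least 1 s when possible
        shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
        for s in shifts:
            yield np.roll(amp, int(s))
    elif scheme == "block_shuffle":
        block = max(int(round(rate)), 1)
        n_blocks = max(n // block, 2)
        bounds = np.array_split(np.arange(n), n_blocks)
        for _ in range(n_surrogates):
            order = rng.permutation(len(bounds))
            yield np.concatenate([amp[bounds[j]] for j in order])
    elif scheme == "full_shuffle":
        for _ in range(n_surrogates):
            yield rng.permutation(amp)
    else:
        raise ValidationError(f"unknown surrogate scheme {scheme!r}")


def surrogate_test(
    series: PhaseAmplitudeSeries,
    method: str = "canolty",
    n_surrogates: int = 200,
    scheme: str = "circular_shift",
    seed: int | None = None,
) -> SurrogateNull:
    """Randomization test of the observed MI against a no-coupling null.

    The default scheme circularly time-shifts the envelope against the phase
    by a uniform random offset of at least 1 s, preserving both marginals and
    the envelope autocorrelation. ``p = (1 + #{null ≥ observed}) /
    (n_surrogates + 1)``.
    """
    if n_surrogates < 19:
        raise ValidationError("need at least 19 surrogates for a 0.05-level test")
    rng = np.random.default_rng(seed)
    observed = _mi_value(series, method)
    eiph = np.exp(1j * series.phase)
    denom = float(np.sqrt(np.mean(series.amplitude**2)))
    null = np.empty(n_surrogates)
    for i, amp_s in enumerate(
        _surrogate_envelopes(series, scheme, n_surrogates, rng)
    ):
        mvl = abs(np.dot(amp_s, eiph)) / series.n
        if method == "normalized":
            mvl = mvl / (np.sqrt(series.n) * denom)
        null[i] = mvl
    p = (1 + int(np.sum(null >= observed))) / (n_surrogates + 1)
    return SurrogateNull(
        scheme=scheme,
        n_surrogates=n_surrogates,
        seed=seed,
        observed=observed,
        null_mi=null,
        p=p,
    )


def default_amp_bandwidth(phase_freq_hz: float) -> float:
    """Amplitude bandwidth wide enough to admit modulation sidebands at f_p."""
    return max(10.0, 2.0 * phase_freq_hz)


def comodulogram(
    samples: np.ndarray,
    rate: float,
    phase_freqs_hz: np.ndarray | None = None,
    amp_freqs_hz: np.ndarray | None = None,
    method: str = "canolty",
    phase_bandwidth_hz: float = 2.0,
    n_surrogates: int = 0,
    scheme: str = "circular_shift",
    seed: int | None = None,
    alpha: float = 0.05,
    edge_trim_s: float = EDGE_TRIM_S,
) -> Comodulogram:
    """MI over a phase-frequency × amplitude-frequency grid.

    Defaults scan phase 3–10 Hz against amplitude 50–120 Hz in 1 Hz steps.
    Each cell band-passes the signal around (f_p ± 1 Hz) and (f_a ± half the
    sideband-admitting bandwidth), extracts phase and envelope, trims edges,
    and computes the requested MI. With ``n_surrogates > 0`` each cell also
    gets a surrogate p-value and the p-matrix is Holm-corrected across cells.
    """
    x = np.asarray(samples, dtype=float)
    pf = np.arange(3.0, 11.0) if phase_freqs_hz is None else np.asarray(phase_freqs_hz, float)
    af = np.arange(50.0, 121.0) if amp_freqs_hz is None else np.asarray(amp_freqs_hz, float)
    nyq = rate / 2
    bw_amp = np.array([default_amp_bandwidth(f) for f in pf])
    if pf.max() + phase_bandwidth_hz / 2 >= nyq or af.max() + bw_amp.max() / 2 >= nyq:
        raise ValidationError("comodulogram grid extends beyond Nyquist")

    mi = np.empty((pf.size, af.size))
    pmat = np.empty((pf.size, af.size)) if n_surrogates else None
    ss = np.random.SeedSequence(seed) if n_surrogates else None
    k = int(round(edge_trim_s * rate))
    sl = slice(k, x.size - k) if k else slice(None)

    for i, fp in enumerate(pf):
        phase = extract_phase(x, rate, (fp - phase_bandwidth_hz / 2, fp + phase_bandwidth_hz / 2))[sl]
        half = bw_amp[i] / 2
        for j, fa in enumerate(af):
            lo, hi = max(fa - half, fp + phase_bandwidth_hz), min(fa + half, 0.99 * nyq)
            amp = extract_amplitude(x, rate, (lo, hi))[sl]
            series = PhaseAmplitudeSeries(
                phase=phase,
                amplitude=amp,
                sampling_rate_hz=rate,
                phase_band_hz=(fp - phase_bandwidth_hz / 2, fp + phase_bandwidth_hz / 2),
                amplitude_band_hz=(lo, hi),
            )
            mi[i, j] = _mi_value(series, method)
            if n_surrogates:
                cell_seed = np.random.SeedSequence(
                    ss.entropy, spawn_key=(i, j)
                ).generate_state(1)[0] % (2**31)
                pmat[i, j] = surrogate_test(
                    series, method, n_surrogates, scheme, int(cell_seed)
                ).p

    significant = None
    if n_surrogates:
        reject, _, _, _ = multipletests(pmat.ravel(), alpha=alpha, method="holm")
        significant = reject.reshape(pmat.shape)
    return Comodulogram(
        phase_freqs_hz=pf,
        amp_freqs_hz=af,
        mi=mi,
        method=method,
        p=pmat,
        significant=significant,
        holm_alpha=alpha if n_surrogates else None,
        phase_bandwidth_hz=phase_bandwidth_hz,
        amp_bandwidths_hz=bw_amp,
    )


def comodulogram_peak(com: Comodulogram) -> tuple[float, float]:
    """Grid cell with the largest MI; ties pick lowest f_p, then lowest f_a."""
    flat = int(np.argmax(com.mi))  # row-major: lowest f_p first, then lowest f_a
    i, j = np.unravel_index(flat, com.mi.shape)
    return float(com.phase_freqs_hz[i]), float(com.amp_freqs_hz[j])
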