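"""Signal conditioning and per-state length standardization.

The conditioning chain is a zero-phase Butterworth band-pass (0.5 Hz
high-pass of order 3, 250 Hz low-pass of order 4) followed by narrow
Butterworth band-stops at 59.5–60.5 Hz and 119.5–120.5 Hz against power-line
contamination and its first harmonic. All filters are applied
forward–backward (``sosfiltfilt``), which doubles the effective order and
cancels phase distortion.

At a 400 Hz sampling rate the Nyquist frequency is 200 Hz, so the nominal
250 Hz low-pass corner is unreachable; the corner is clamped to
0.99 × Nyquist with a warning, which leaves the low-pass effectively
inactive — consistent with the settings it reproduces.

Because coupling and density statistics are duration-dependent, per-state
concatenations are trimmed to fixed standard lengths (wake 15,000 s,
NREM 10,000 s, REM 2,000 s by default); too little data raises a typed
shortfall error rather than producing a short file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import ShortfallError, ValidationError, warn

__all__ = [
    "FilterSpec",
    "StandardizationSpec",
    "bandpass_filter",
    "notch_filter",
    "concatenate_and_trim",
    "standardize_state",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + band-stop settings (defaults are the standard chain)."""

    highpass_hz: float = 0.5
    highpass_order: int = 3
    lowpass_hz: float = 250.0
    lowpass_order: int = 4
    stop_bands: tuple[tuple[float, float], ...] = ((59.5, 60.5), (119.5, 120.5))
    stop_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValidationError("need 0 < high-pass corner < low-pass corner")
        for lo, hi in self.stop_bands:
            if not 0 < lo < hi:
                raise ValidationError(f"bad stop band ({lo}, {hi})")


@dataclass(frozen=True)
class StandardizationSpec:
    """Per-state standardized durations in seconds."""

    targets_s: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 15_000.0, "NREM": 10_000.0, "REM": 2_000.0}
    )

    def __post_init__(self) -> None:
        for state, t in self.targets_s.items():
            if t <= 0:
                raise ValidationError(f"target duration for {state} must be positive")


def _effective_lowpass(spec: FilterSpec, rate: float) -> float:
    nyq = rate / 2
    if spec.lowpass_hz >= nyq:
        corner = 0.99 * nyq
        warn(
            f"low-pass corner {spec.lowpass_hz:g} Hz is at or above Nyquist "
            f"({nyq:g} Hz); clamping to {corner:g} Hz"
        )
        return corner
    return spec.lowpass_hz


def bandpass_filter(
    samples: np.ndarray, rate: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; removes DC, preserves length."""
    x = np.asarray(samples, dtype=float)
    if rate <= 2 * spec.highpass_hz:
        raise ValidationError("sampling rate must exceed twice the high-pass corner")
    hp = signal.butter(
        spec.highpass_order, spec.highpass_hz, btype="highpass", fs=rate, output="sos"
    )
    lp = signal.butter(
        spec.lowpass_order,
        _effective_lowpass(spec, rate),
        btype="lowpass",
        fs=rate,
        output="sos",
    )
    return signal.sosfiltfilt(lp, signal.sosfiltfilt(hp, x))


def notch_filter(
    samples: np.ndarray,
    rate: float,
    stop_bands: tuple[tuple[float, float], ...] = ((59.5, 60.5), (119.5, 120.5)),
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-stops at the given intervals."""
    x = np.asarray(samples, dtype=float)
    nyq = rate / 2
    for lo, hi in stop_bands:
        if not 0 < lo < hi < nyq:
            raise ValidationError(
                f"stop band ({lo}, {hi}) Hz must lie inside (0, {nyq:g}) Hz"
            )
        sos = signal.butter(order, [lo, hi], btype="bandstop", fs=rate, output="sos")
        x = signal.sosfiltfilt(sos, x)
    return x


def condition(
    samples: np.ndarray, rate: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Full conditioning chain: band-pass then band-stop intervals."""
    return notch_filter(
        bandpass_filter(samples, rate, spec), rate, spec.stop_bands, spec.stop_order
    )


def concatenate_and_trim(
    segments: list[np.ndarray],
    target_duration_s: float,
    rate: float,
    state: str = "",
) -> np.ndarray:
    """Concatenate segments in order and trim the tail to the target length.

    Raises :class:`ShortfallError` reporting available vs required seconds if
    the segments are too short. Trimming an exact-length input is the
    identity.
    """
    if target_duration_s <= 0:
        raise ValidationError("target duration must be positive")
    need = target_duration_s * rate
    if abs(need - round(need)) > 1e-9:
        raise ValidationError("target duration × rate must be an integer sample count")
    need = int(round(need))
    total = sum(int(s.size) for s in segments)
    if total < need:
        raise ShortfallError(state or "requested", total / rate, target_duration_s)
    if not segments:  # pragma: no cover - need==0 excluded above
        return np.empty(0)
    out = np.concatenate([np.asarray(s, dtype=float) for s in segments])
    return out[:need]


def standardize_state(
    segments: list[np.ndarray],
    state: str,
    rate: float,
    spec: StandardizationSpec = StandardizationSpec(),
    filter_spec: FilterSpec | None = FilterSpec(),
) -> np.ndarray:
    """Concatenate → trim to the state's standard length → condition.

    Concatenation happens before filtering, matching the processing order of
    the original chain; windows spanning concatenation seams are kept (see
    the methods note).
    """
    if state not in spec.targets_s:
        raise ValidationError(f"no standardized duration configured for {state!r}")
    x = concatenate_and_trim(segments, spec.targets_s[state], rate, state)
    if filter_spec is not None:
        x = condition(x, rate, filter_spec)
    return x
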