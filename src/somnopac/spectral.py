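"""Welch power spectral densities and band-power summaries.

PSDs use Welch's method with a 1-s Hann window and 25% overlap (overlap as a
fraction of the window length), giving a 1 Hz frequency resolution at any
integer sampling rate. Band powers are rectangle-rule integrals of the
density over half-open bands ``[lo, hi)``.

Two band presets circulate in the sleep-EEG literature and both are
provided: the ``figure`` preset (delta 1–4, theta 4–8, alpha 8–13, beta
13–30, gamma 30–50 Hz) is the default; the ``methods`` preset widens delta
to 0.5 Hz and gamma to 200 Hz. They are selected explicitly, never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import ValidationError

__all__ = [
    "PSD",
    "BandDefinition",
    "BAND_PRESETS",
    "welch_psd",
    "band_power",
    "peak_power",
    "compare_distributions",
]


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [lo, hi)."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValidationError(f"band {self.name}: need lo < hi")


BAND_PRESETS: dict[str, tuple[BandDefinition, ...]] = {
    "figure": (
        BandDefinition("delta", 1.0, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("gamma", 30.0, 50.0),
    ),
    "methods": (
        BandDefinition("delta", 0.5, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("gamma", 30.0, 200.0),
    ),
}


@dataclass
class PSD:
    """One-sided Welch power spectral density (µV²/Hz)."""

    frequencies_hz: np.ndarray
    density: np.ndarray
    window_s: float = 1.0
    overlap_fraction: float = 0.25
    state: str = ""
    subject_id: str = ""
    taper: str = "hann"

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.frequencies_hz.shape != self.density.shape:
            raise ValidationError("frequency grid and density must match in shape")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if (self.density < 0).any():
            raise ValidationError("densities must be non-negative")

    @property
    def df(self) -> float:
        return float(self.frequencies_hz[1] - self.frequencies_hz[0])

    def total_power(self) -> float:
        return float(self.density.sum() * self.df)


def welch_psd(
    samples: np.ndarray,
    rate: float,
    window_s: float = 1.0,
    overlap: float = 0.25,
    **labels,
) -> PSD:
    """Welch PSD with a Hann taper; overlap is a fraction of the window."""
    x = np.asarray(samples, dtype=float)
    nperseg = int(round(window_s * rate))
    if x.size < nperseg:
        raise ValidationError(
            f"signal of {x.size} samples is shorter than one {nperseg}-sample window"
        )
    if not 0 <= overlap < 1:
        raise ValidationError("overlap fraction must lie in [0, 1)")
    freqs, den = sps.welch(
        x,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
    )
    return PSD(
        frequencies_hz=freqs,
        density=den,
        window_s=window_s,
        overlap_fraction=overlap,
        **labels,
    )


def band_power(psd: PSD, band: BandDefinition) -> float:
    """Rectangle-rule integral of the density over ``[lo, hi)`` (µV²)."""
    f = psd.frequencies_hz
    if band.lo_hz < f[0] or band.hi_hz > f[-1] + psd.df:
        raise ValidationError(
            f"band [{band.lo_hz}, {band.hi_hz}) Hz lies outside the grid "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    mask = (f >= band.lo_hz) & (f < band.hi_hz)
    return float(psd.density[mask].sum() * psd.df)


def peak_power(
    psd: PSD, frequency_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """(frequency, density) of the maximum density; ties pick the lowest frequency."""
    f = psd.frequencies_hz
    if frequency_range is None:
        mask = np.ones_like(f, dtype=bool)
    else:
        lo, hi = frequency_range
        mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise ValidationError("frequency range selects no grid points")
    sub_f = f[mask]
    sub_d = psd.density[mask]
    i = int(np.argmax(sub_d))  # first occurrence = lowest frequency on ties
    return float(sub_f[i]), float(sub_d[i])


def compare_distributions(psd_a: PSD, psd_b: PSD) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on the per-frequency density values.

    Returns ``(D, p)``. Both PSDs must share a frequency grid.
    """
    if not np.array_equal(psd_a.frequencies_hz, psd_b.frequencies_hz):
        raise ValidationError("PSDs must share a frequency grid")
    res = stats.ks_2samp(psd_a.density, psd_b.density, method="auto")
    return float(res.statistic), float(res.pvalue)
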