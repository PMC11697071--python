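"""Epoch scoring and sleep-architecture metrics.

Scoring is a transparent three-rule decision tree over per-epoch features,
mirroring the conventional criteria: high EMG tone → WAKE; otherwise a
delta-dominant EEG → NREM; otherwise a theta-dominant, low-voltage EEG →
REM; anything left falls back to NREM (the majority sleep state). It is a
reproducible stand-in for manual scoring, with every threshold in config.

Architecture metrics follow the usual light/dark split: per 12-h block and
state, percent time, mean bout duration, the 3×3 transition count matrix,
and arousal counts (NREM→WAKE and REM→WAKE), reported both raw per block
and per hour spent in the origin state. A bout spanning a block boundary is
attributed to the block containing its onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import STATES, Hypnogram, Recording, ValidationError
from .signal_io import state_runs
from .spectral import BandDefinition, band_power, welch_psd

__all__ = [
    "ScoringThresholds",
    "EpochFeatures",
    "ArchitectureSummary",
    "compute_epoch_features",
    "score_epochs",
    "extract_bouts",
    "summarize_architecture",
]

extract_bouts = state_runs

_DELTA = BandDefinition("delta", 0.5, 4.0)
_THETA = BandDefinition("theta", 4.0, 9.0)
_TOTAL = BandDefinition("total", 0.5, 50.0)


@dataclass(frozen=True)
class ScoringThresholds:
    """Decision-tree cuts (calibrated on the synthetic presets)."""

    emg_wake_cut_uv: float = 18.0
    delta_fraction_cut: float = 0.5
    theta_delta_ratio_cut: float = 1.5
    eeg_rms_cut_uv: float = 80.0


@dataclass
class EpochFeatures:
    """Per-epoch EEG/EMG summary features (one row per hypnogram epoch)."""

    eeg_rms_uv: np.ndarray
    delta_fraction: np.ndarray
    theta_delta_ratio: np.ndarray
    emg_rms_uv: np.ndarray
    epoch_length_s: float = 10.0

    @property
    def n_epochs(self) -> int:
        return int(self.eeg_rms_uv.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eeg_rms_uv": self.eeg_rms_uv,
                "delta_fraction": self.delta_fraction,
                "theta_delta_ratio": self.theta_delta_ratio,
                "emg_rms_uv": self.emg_rms_uv,
            }
        )


def compute_epoch_features(
    recording: Recording,
    epoch_length_s: float = 10.0,
    eeg_channel: str = "EEG1",
) -> EpochFeatures:
    """EEG RMS, delta fraction, theta/delta ratio, and EMG RMS per epoch.

    Band powers come from a 1-s Welch PSD of each epoch; the delta fraction
    is delta power over total 0.5–50 Hz power.
    """
    rate = recording.sampling_rate_hz
    n_per = epoch_length_s * rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValidationError("epoch length × rate must be an integer sample count")
    n_per = int(round(n_per))
    eeg = recording.channel(eeg_channel)
    emg = recording.channel("EMG")
    n_epochs = eeg.size // n_per
    if n_epochs < 1:
        raise ValidationError("recording is shorter than one epoch")

    eeg_rms = np.empty(n_epochs)
    delta_frac = np.empty(n_epochs)
    theta_delta = np.empty(n_epochs)
    emg_rms = np.empty(n_epochs)
    for i in range(n_epochs):
        seg = eeg[i * n_per : (i + 1) * n_per]
        psd = welch_psd(seg, rate)
        delta = band_power(psd, _DELTA)
        theta = band_power(psd, _THETA)
        total = band_power(psd, _TOTAL)
        eeg_rms[i] = np.sqrt(np.mean(seg**2))
        delta_frac[i] = delta / total if total > 0 else 0.0
        theta_delta[i] = theta / delta if delta > 0 else np.inf
        emg_rms[i] = np.sqrt(np.mean(emg[i * n_per : (i + 1) * n_per] ** 2))
    return EpochFeatures(
        eeg_rms_uv=eeg_rms,
        delta_fraction=delta_frac,
        theta_delta_ratio=theta_delta,
        emg_rms_uv=emg_rms,
        epoch_length_s=epoch_length_s,
    )


def score_epochs(
    features: EpochFeatures,
    thresholds: ScoringThresholds = ScoringThresholds(),
    smooth_epochs: int = 0,
) -> Hypnogram:
    """Rule-based scoring of epochs into WAKE/NREM/REM.

    Rule precedence: EMG above the wake cut forces WAKE regardless of EEG
    features; else delta-dominant epochs are NREM; else theta-dominant,
    low-voltage epochs are REM; else NREM (fallback). Optional smoothing
    relabels isolated runs shorter than ``smooth_epochs``.
    """
    labels = np.full(features.n_epochs, "NREM", dtype="<U4")
    wake = features.emg_rms_uv > thresholds.emg_wake_cut_uv
    nrem = ~wake & (features.delta_fraction > thresholds.delta_fraction_cut)
    rem = (
        ~wake
        & ~nrem
        & (features.theta_delta_ratio > thresholds.theta_delta_ratio_cut)
        & (features.eeg_rms_uv < thresholds.eeg_rms_cut_uv)
    )
    labels[wake] = "WAKE"
    labels[rem] = "REM"
    hyp = Hypnogram(states=labels, epoch_length_s=features.epoch_length_s)
    if smooth_epochs > 0:
        hyp = _smooth(hyp, smooth_epochs)
    return hyp


def _smooth(hypnogram: Hypnogram, min_epochs: int) -> Hypnogram:
    """Absorb runs shorter than ``min_epochs`` into the preceding state."""
    labels = hypnogram.states.copy()
    for bout in state_runs(hypnogram):
        if bout.n_epochs < min_epochs and bout.start_epoch > 0:
            labels[bout.start_epoch : bout.start_epoch + bout.n_epochs] = labels[
                bout.start_epoch - 1
            ]
    return Hypnogram(states=labels, epoch_length_s=hypnogram.epoch_length_s)


@dataclass
class BlockSummary:
    """Architecture metrics for one light/dark block."""

    block_index: int
    block_label: str
    n_epochs: int
    percent_time: dict[str, float]
    mean_bout_duration_s: dict[str, float]
    bout_counts: dict[str, int]
    transition_counts: np.ndarray  # 3x3, STATES order, from -> to
    arousals: dict[str, int]  # {"NREM->WAKE": ..., "REM->WAKE": ...}
    arousals_per_origin_hour: dict[str, float]


@dataclass
class ArchitectureSummary:
    """Per-block architecture metrics with a tidy-table exporter."""

    blocks: list[BlockSummary] = field(default_factory=list)
    epoch_length_s: float = 10.0

    def to_frame(self, subject_id: str = "", group: str = "") -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            for state in STATES:
                rows.append((b.block_index, b.block_label, state, "percent_time",
                             b.percent_time[state]))
                rows.append((b.block_index, b.block_label, state,
                             "mean_bout_duration_s", b.mean_bout_duration_s[state]))
            for key, v in b.arousals.items():
                rows.append((b.block_index, b.block_label, key.split("->")[0],
                             "arousals", float(v)))
            for key, v in b.arousals_per_origin_hour.items():
                rows.append((b.block_index, b.block_label, key.split("->")[0],
                             "arousals_per_origin_hour", v))
        df = pd.DataFrame(
            rows, columns=["block", "block_label", "state", "metric", "value"]
        )
        if subject_id:
            df.insert(0, "subject", subject_id)
        if group:
            df.insert(1, "group", group)
        return df


def summarize_architecture(
    hypnogram: Hypnogram,
    block_hours: float = 12.0,
    first_block: str = "light",
) -> ArchitectureSummary:
    """Split the hypnogram into light/dark blocks and summarize each.

    The recording is assumed to start at a block boundary (light onset by
    default); blocks alternate light/dark. Bouts are attributed to the block
    containing their onset; a trailing partial block is summarized as-is.
    """
    if first_block not in ("light", "dark"):
        raise ValidationError("first_block must be 'light' or 'dark'")
    epochs_per_block = block_hours * 3600 / hypnogram.epoch_length_s
    if abs(epochs_per_block - round(epochs_per_block)) > 1e-9:
        raise ValidationError("block length must be a whole number of epochs")
    epochs_per_block = int(round(epochs_per_block))
    n = len(hypnogram)
    if n < epochs_per_block:
        raise ValidationError(
            f"hypnogram of {n} epochs does not cover one {block_hours}-h block"
        )
    bouts = state_runs(hypnogram)
    codes = hypnogram.codes()
    labels = ("light", "dark") if first_block == "light" else ("dark", "light")

    summary = ArchitectureSummary(epoch_length_s=hypnogram.epoch_length_s)
    n_blocks = int(np.ceil(n / epochs_per_block))
    for k in range(n_blocks):
        a, b = k * epochs_per_block, min((k + 1) * epochs_per_block, n)
        block_codes = codes[a:b]
        n_block = b - a
        pct = {
            s: 100.0 * np.count_nonzero(block_codes == i) / n_block
            for i, s in enumerate(STATES)
        }
        block_bouts = [bt for bt in bouts if a <= bt.start_epoch < b]
        mean_dur = {}
        counts = {}
        for s in STATES:
            durs = [bt.duration_s for bt in block_bouts if bt.state == s]
            counts[s] = len(durs)
            mean_dur[s] = float(np.mean(durs)) if durs else 0.0
        trans = np.zeros((3, 3), dtype=int)
        # transitions whose *origin* epoch lies in the block
        upto = min(b, n - 1)
        for i in range(a, upto):
            if codes[i] != codes[i + 1]:
                trans[codes[i], codes[i + 1]] += 1
        arousals = {
            "NREM->WAKE": int(trans[1, 0]),
            "REM->WAKE": int(trans[2, 0]),
        }
        hours_in_state = {
            s: np.count_nonzero(block_codes == i) * hypnogram.epoch_length_s / 3600.0
            for i, s in enumerate(STATES)
        }
        per_hour = {
            key: (v / hours_in_state[key.split("->")[0]]
                  if hours_in_state[key.split("->")[0]] > 0 else 0.0)
            for key, v in arousals.items()
        }
        summary.blocks.append(
            BlockSummary(
                block_index=k,
                block_label=labels[k % 2],
                n_epochs=n_block,
                percent_time=pct,
                mean_bout_duration_s=mean_dur,
                bout_counts=counts,
                transition_counts=trans,
                arousals=arousals,
                arousals_per_origin_hour=per_hour,
            )
        )
    return summary
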