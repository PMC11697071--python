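"""Core domain types shared across the pipeline.

A :class:`Recording` is a multi-channel voltage time series (two differential
EEG leads and one nuchal EMG lead in the standard rodent montage) sampled at a
single rate. A :class:`Hypnogram` is the epoch-by-epoch sequence of vigilance
state labels (WAKE / NREM / REM) aligned to a recording; the standard scoring
epoch is 10 s. A :class:`Bout` is a maximal run of consecutive epochs in one
state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

#: Closed vigilance-state alphabet, in transition-matrix row/column order.
STATES: tuple[str, ...] = ("WAKE", "NREM", "REM")
STATE_TO_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

#: Channel roles the analysis understands.
ROLES: tuple[str, ...] = ("EEG1", "EEG2", "EMG")


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class FormatError(ValueError):
    """A file on disk does not conform to its declared format."""


class ShortfallError(ValidationError):
    """Not enough data to reach a requested standardized duration."""

    def __init__(self, state: str, available_s: float, required_s: float):
        self.state = state
        self.available_s = available_s
        self.required_s = required_s
        super().__init__(
            f"insufficient {state} data: {available_s:g} s available, "
            f"{required_s:g} s required (shortfall {required_s - available_s:g} s)"
        )


def infer_channel_roles(labels: tuple[str, ...] | list[str]) -> dict[str, int]:
    """Assign EEG1/EEG2/EMG roles by case-insensitive label match, in index order.

    Labels containing ``EMG`` take the EMG role; labels containing ``EEG`` fill
    EEG1 then EEG2. An explicit mapping passed to :class:`Recording` overrides
    this inference.
    """
    roles: dict[str, int] = {}
    eeg_count = 0
    for i, lab in enumerate(labels):
        up = lab.upper()
        if "EMG" in up and "EMG" not in roles:
            roles["EMG"] = i
        elif "EEG" in up and eeg_count < 2:
            eeg_count += 1
            roles[f"EEG{eeg_count}"] = i
    if "EEG1" not in roles:
        raise ValidationError(
            f"could not infer an EEG channel from labels {list(labels)}; "
            "pass an explicit roles mapping"
        )
    return roles


@dataclass
class Recording:
    """Multi-channel voltage time series with channel-role metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in nominal microvolts, one row per channel.
    channel_labels : sequence of str
        One label per row of ``data``.
    sampling_rate_hz : float
        Common sampling rate of all channels (400 Hz for the standard rig).
    roles : dict, optional
        Explicit ``role -> channel index`` mapping; inferred from labels when
        omitted.
    """

    data: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate_hz: float
    subject_id: str = "subject-0"
    group: str = ""
    start_time: datetime | None = None
    roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (n_channels, n_samples)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValidationError("recording contains NaN samples")
        if not self.roles:
            self.roles = infer_channel_roles(self.channel_labels)
        for role, idx in self.roles.items():
            if not 0 <= idx < self.data.shape[0]:
                raise ValidationError(f"role {role!r} maps to invalid channel {idx}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, role: str) -> np.ndarray:
        """Return the samples of the channel holding ``role`` (e.g. ``"EEG1"``)."""
        if role not in self.roles:
            raise ValidationError(f"recording has no channel with role {role!r}")
        return self.data[self.roles[role]]


@dataclass
class Hypnogram:
    """Epoch-wise state labels aligned to a recording.

    ``offset_s`` is the start of epoch 0 relative to the recording start;
    it is 0 unless the scoring file states otherwise.
    """

    states: np.ndarray
    epoch_length_s: float = 10.0
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U4")
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValidationError("hypnogram must be a non-empty 1-D label sequence")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValidationError(f"unknown state labels: {sorted(bad)}")
        if not self.epoch_length_s > 0:
            raise ValidationError("epoch length must be positive")

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def codes(self) -> np.ndarray:
        """Integer codes in :data:`STATES` order."""
        lut = {s: i for i, s in enumerate(STATES)}
        return np.fromiter((lut[s] for s in self.states), dtype=np.int64, count=len(self))

    def check_alignment(self, recording: Recording) -> None:
        if self.offset_s + self.duration_s > recording.duration_s + 1e-9:
            raise ValidationError(
                f"hypnogram spans {self.offset_s + self.duration_s:g} s but the "
                f"recording lasts only {recording.duration_s:g} s"
            )


@dataclass(frozen=True)
class Bout:
    """Maximal run of consecutive epochs in one state."""

    state: str
    start_epoch: int
    n_epochs: int
    duration_s: float


def validate_transition_matrix(matrix: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Validate and return a row-stochastic 3x3 matrix over :data:`STATES`."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValidationError(f"transition matrix must be 3x3, got {m.shape}")
    if (m < 0).any():
        raise ValidationError("transition probabilities must be non-negative")
    rowsum = m.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=atol, rtol=0):
        raise ValidationError(f"transition-matrix rows must sum to 1, got {rowsum}")
    return m


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
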