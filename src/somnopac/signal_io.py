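"""Reading and writing recordings (EDF) and hypnograms (TSV).

The EDF dialect is plain EDF: a 256-byte fixed header, 256 bytes per signal,
then little-endian 16-bit data records. EDF+ annotation channels are ignored
with a warning. Samples are stored per the header's physical/digital ranges,
so a write→read round trip is exact to one 16-bit quantization step.

Hypnograms travel as three-column TSV: ``epoch_index``, ``onset_s``,
``state`` with states drawn from {WAKE, NREM, REM}; epoch 0 starts at the
recording start unless ``onset_s`` of the first row says otherwise.
"""

from __future__ import annotations

import os
from datetime import datetime

import numpy as np
import pandas as pd

from .core import (
    STATES,
    Bout,
    FormatError,
    Hypnogram,
    Recording,
    ValidationError,
    warn,
)

__all__ = [
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "export_state_segments",
]

_HDR = 256  # bytes of fixed header, and per-signal header block


def _ascii(field: bytes, path: str, offset: int) -> str:
    try:
        return field.decode("ascii").strip()
    except UnicodeDecodeError as e:
        raise FormatError(
            f"{path}: non-ASCII header field at byte offset {offset}: {e}"
        ) from None


def _num(field: bytes, path: str, offset: int, kind=float):
    text = _ascii(field, path, offset)
    try:
        return kind(float(text)) if kind is int else kind(text)
    except ValueError:
        raise FormatError(
            f"{path}: unparseable numeric header field {text!r} at byte offset {offset}"
        ) from None


def read_edf(path: str | os.PathLike, roles: dict[str, int] | None = None) -> Recording:
    """Read a plain EDF file into a :class:`Recording`.

    Channel roles (EEG1/EEG2/EMG) are inferred from signal labels; pass
    ``roles`` to override. Malformed or truncated files raise
    :class:`FormatError` naming the byte offset — never a partial recording.
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise FormatError(
                f"{path}: truncated fixed header (got {len(head)} of {_HDR} bytes)"
            )
        n_records = _num(head[236:244], path, 236, int)
        record_dur = _num(head[244:252], path, 244)
        n_signals = _num(head[252:256], path, 252, int)
        if n_signals < 1:
            raise FormatError(f"{path}: header declares {n_signals} signals")
        header_bytes = _num(head[184:192], path, 184, int)
        expected_header = _HDR * (1 + n_signals)
        if header_bytes != expected_header:
            raise FormatError(
                f"{path}: header-size field says {header_bytes} bytes but "
                f"{n_signals} signals imply {expected_header} (byte offset 184)"
            )
        sig_head = fh.read(_HDR * n_signals)
        if len(sig_head) < _HDR * n_signals:
            raise FormatError(
                f"{path}: truncated signal headers at byte offset {_HDR + len(sig_head)}"
            )

        # signal headers are field-major: all labels, then all transducers, ...
        off = 0
        blocks = {}
        for name, width in (
            ("label", 16),
            ("transducer", 80),
            ("dimension", 8),
            ("phys_min", 8),
            ("phys_max", 8),
            ("dig_min", 8),
            ("dig_max", 8),
            ("prefilter", 80),
            ("n_samples", 8),
            ("reserved", 32),
        ):
            blocks[name] = off
            off += width

        def read_block(name: str, width: int, kind):
            base = blocks[name] * n_signals
            return [
                _num(sig_head[base + i * width : base + (i + 1) * width], path,
                     _HDR + base + i * width, kind)
                for i in range(n_signals)
            ]

        labels = [
            _ascii(sig_head[i * 16 : (i + 1) * 16], path, _HDR + i * 16)
            for i in range(n_signals)
        ]
        phys_min = read_block("phys_min", 8, float)
        phys_max = read_block("phys_max", 8, float)
        dig_min = read_block("dig_min", 8, int)
        dig_max = read_block("dig_max", 8, int)
        spr = read_block("n_samples", 8, int)

        record_samples = sum(spr)
        payload = fh.read()
    if n_records < 0:
        if record_samples == 0 or len(payload) % (2 * record_samples):
            raise FormatError(
                f"{path}: record count unknown and payload of {len(payload)} bytes "
                f"is not a whole number of {2 * record_samples}-byte records"
            )
        n_records = len(payload) // (2 * record_samples)
    expected = n_records * record_samples * 2
    if len(payload) != expected:
        raise FormatError(
            f"{path}: expected {expected} data bytes ({n_records} records) but found "
            f"{len(payload)}; file truncated near byte offset "
            f"{expected_header + len(payload)}"
        )
    raw = np.frombuffer(payload, dtype="<i2").reshape(n_records, record_samples)

    keep = [i for i, lab in enumerate(labels) if lab != "EDF Annotations"]
    if len(keep) < n_signals:
        warn(f"{path}: ignoring {n_signals - len(keep)} EDF+ annotation channel(s)")

    bounds = np.cumsum([0] + spr)
    data = []
    for i in keep:
        dig = raw[:, bounds[i] : bounds[i + 1]].reshape(-1).astype(float)
        if dig_max[i] == dig_min[i]:
            raise FormatError(
                f"{path}: signal {i} has degenerate digital range (byte offset "
                f"{_HDR + blocks['dig_min'] * n_signals + i * 8})"
            )
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data.append(phys_min[i] + (dig - dig_min[i]) * scale)
    lengths = {len(d) for d in data}
    if len(lengths) > 1:
        raise ValidationError(
            f"{path}: channels have unequal sample counts {sorted(lengths)}; "
            "mixed sampling rates are not supported"
        )

    start = None
    try:
        d = _ascii(head[168:176], path, 168)
        t = _ascii(head[176:184], path, 176)
        day, mon, yy = (int(x) for x in d.split("."))
        hh, mm, sec = (int(x) for x in t.split("."))
        year = 2000 + yy if yy < 85 else 1900 + yy
        start = datetime(year, mon, day, hh, mm, sec)
    except (ValueError, FormatError):
        pass

    spr0 = spr[keep[0]]
    rate = spr0 / record_dur
    return Recording(
        data=np.vstack(data),
        channel_labels=tuple(labels[i] for i in keep),
        sampling_rate_hz=rate,
        subject_id=_ascii(head[8:88], path, 8) or "unknown",
        group=_ascii(head[88:168], path, 88),
        start_time=start,
        roles=roles or {},
    )


def _fit(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    recording: Recording,
    path: str | os.PathLike,
    physical_range: tuple[float, float] = (-1000.0, 1000.0),
    record_duration_s: float = 1.0,
) -> None:
    """Write a :class:`Recording` as plain EDF.

    Samples must lie within ``physical_range`` (validation error otherwise —
    no silent clipping) and the recording must span a whole number of data
    records.
    """
    path = os.fspath(path)
    data = recording.data
    if np.isnan(data).any():
        raise ValidationError("cannot write NaN samples to EDF")
    pmin, pmax = physical_range
    if not pmin < pmax:
        raise ValidationError("physical range must be increasing")
    if data.min() < pmin or data.max() > pmax:
        raise ValidationError(
            f"samples in [{data.min():g}, {data.max():g}] exceed the declared "
            f"physical range [{pmin:g}, {pmax:g}]"
        )
    spr = recording.sampling_rate_hz * record_duration_s
    if abs(spr - round(spr)) > 1e-9:
        raise ValidationError("sampling rate × record duration must be an integer")
    spr = int(round(spr))
    n_records = data.shape[1] / spr
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValidationError(
            f"recording length {data.shape[1]} is not a whole number of "
            f"{spr}-sample records"
        )
    n_records = int(round(n_records))
    ns = data.shape[0]

    dmin, dmax = -32768, 32767
    dig = np.rint((data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    dig = dig.astype("<i2")

    start = recording.start_time or datetime(2000, 1, 1, 0, 0, 0)
    head = b"".join(
        [
            _fit("0", 8),
            _fit(recording.subject_id, 80),
            _fit(recording.group, 80),
            _fit(start.strftime("%d.%m.%y"), 8),
            _fit(start.strftime("%H.%M.%S"), 8),
            _fit(str(_HDR * (1 + ns)), 8),
            _fit("", 44),
            _fit(str(n_records), 8),
            _fit(f"{record_duration_s:g}", 8),
            _fit(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_fit(lab, 16) for lab in recording.channel_labels),
            b"".join(_fit("", 80) for _ in range(ns)),
            b"".join(_fit("uV", 8) for _ in range(ns)),
            b"".join(_fit(f"{pmin:g}", 8) for _ in range(ns)),
            b"".join(_fit(f"{pmax:g}", 8) for _ in range(ns)),
            b"".join(_fit(str(dmin), 8) for _ in range(ns)),
            b"".join(_fit(str(dmax), 8) for _ in range(ns)),
            b"".join(_fit("", 80) for _ in range(ns)),
            b"".join(_fit(str(spr), 8) for _ in range(ns)),
            b"".join(_fit("", 32) for _ in range(ns)),
        ]
    )
    # interleave: record-major, signal-blocked
    payload = (
        dig.reshape(ns, n_records, spr).transpose(1, 0, 2).tobytes()
    )
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig)
        fh.write(payload)


def read_hypnogram(path: str | os.PathLike) -> Hypnogram:
    """Read an ``epoch_index / onset_s / state`` TSV into a :class:`Hypnogram`."""
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t")
    required = {"epoch_index", "onset_s", "state"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: empty hypnogram")
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(df))):
        bad = int(np.flatnonzero(idx != np.arange(len(df)))[0])
        raise ValidationError(
            f"{path}: epoch_index must be contiguous from 0; first break at row {bad}"
        )
    states = df["state"].astype(str).to_numpy()
    bad_mask = ~np.isin(states, STATES)
    if bad_mask.any():
        row = int(np.flatnonzero(bad_mask)[0])
        raise ValidationError(
            f"{path}: unknown state token {states[row]!r} at line {row + 2}"
        )
    onset = df["onset_s"].to_numpy(dtype=float)
    if len(df) > 1:
        steps = np.diff(onset)
        if not np.allclose(steps, steps[0], atol=1e-6):
            raise ValidationError(f"{path}: onsets are not evenly spaced")
        epoch_len = float(steps[0])
    else:
        epoch_len = 10.0
    return Hypnogram(states=states, epoch_length_s=epoch_len, offset_s=float(onset[0]))


def write_hypnogram(hypnogram: Hypnogram, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    n = len(hypnogram)
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "onset_s": hypnogram.offset_s
            + np.arange(n) * hypnogram.epoch_length_s,
            "state": hypnogram.states,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def state_runs(hypnogram: Hypnogram) -> list[Bout]:
    """Maximal-run decomposition of a hypnogram (shared with sleep_architecture)."""
    codes = hypnogram.codes()
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    return [
        Bout(
            state=STATES[codes[s0]],
            start_epoch=int(s0),
            n_epochs=int(s1 - s0),
            duration_s=float((s1 - s0) * hypnogram.epoch_length_s),
        )
        for s0, s1 in zip(starts, ends)
    ]


def export_state_segments(
    recording: Recording,
    hypnogram: Hypnogram,
    state: str,
    channel: str = "EEG1",
) -> list[np.ndarray]:
    """Extract the maximal runs of one state as contiguous sample slices.

    Segments come back in temporal order; each spans exactly
    ``run_length × epoch_length × rate`` samples of the requested channel.
    A state absent from the hypnogram yields an empty list.
    """
    if state not in STATES:
        raise ValidationError(f"unknown state {state!r}")
    hypnogram.check_alignment(recording)
    x = recording.channel(channel)
    rate = recording.sampling_rate_hz
    epoch_n = hypnogram.epoch_length_s * rate
    if abs(epoch_n - round(epoch_n)) > 1e-9:
        raise ValidationError("epoch length × rate must be an integer sample count")
    epoch_n = int(round(epoch_n))
    off = int(round(hypnogram.offset_s * rate))
    out = []
    for bout in state_runs(hypnogram):
        if bout.state != state:
            continue
        a = off + bout.start_epoch * epoch_n
        b = a + bout.n_epochs * epoch_n
        out.append(x[a:b])
    return out
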