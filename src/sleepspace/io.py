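"""Polysomnography I/O: EDF recordings and stage-per-epoch hypnograms.

Recordings are read from EDF (European Data Format) through MNE; a minimal
EDF writer is provided so that synthetic recordings round-trip through the
same container real polysomnographs use. Hypnograms are flat CSV tables
(``epoch_start_s,stage``) — inspectable and diffable.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical stage order used everywhere (tie-breaks, report columns).
STAGES: tuple[str, ...] = ("WAKE", "NREM1", "NREM2", "NREM3", "REM")
UNSCORED = "UNSCORED"
_VALID_STAGES = set(STAGES) | {UNSCORED}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


@dataclass
class Recording:
    """Multichannel EEG signal in microvolts.

    Attributes
    ----------
    channel_labels : list of str
        One label per channel (e.g. ``["F3", "F4", "C3", "C4", "O1", "O2"]``).
    sampling_rate : float
        Samples per second; shared by all channels.
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    channel_labels: list[str]
    sampling_rate: float
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (n_channels, n_samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.signal.shape[0]} channels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the sample series of one channel by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording "
                           f"(has {self.channel_labels})") from None
        return self.signal[idx]


@dataclass
class Hypnogram:
    """Sleep-stage labels on a fixed epoch grid."""

    epoch_length: float
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if not self.epoch_length > 0:
            raise ValueError("epoch_length must be positive")
        bad = set(self.labels) - _VALID_STAGES
        if bad:
            raise ValueError(f"unknown stage symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return self.epoch_length == other.epoch_length and (
            len(self.labels) == len(other.labels)
            and bool(np.all(self.labels == other.labels))
        )


# ---------------------------------------------------------------------------
# EDF


def _edf_header_fields(path: Path) -> tuple[int, int, float, list[str], list[int]]:
    """Parse the ASCII EDF header: (n_records, n_signals, record_dur,
    labels, samples_per_record)."""
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        n_records = int(fixed[236:244].decode("ascii").strip())
        record_dur = float(fixed[244:252].decode("ascii").strip())
        ns = int(fixed[252:256].decode("ascii").strip())
        if ns < 1:
            raise FormatError(f"{path}: EDF file declares zero signals")
        var = fh.read(ns * 256)
        labels = [var[16 * i : 16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
        off = ns * (16 + 80 + 8 * 5 + 80)
        spr = [
            int(var[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
            for i in range(ns)
        ]
    return n_records, ns, record_dur, labels, spr


def read_recording(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    Channels must share a single sampling rate; a mixed-rate file is
    rejected (resampling would desynchronise the spectral bins the
    band-ratio comparison relies on).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _, ns, record_dur, labels, spr = _edf_header_fields(path)
    data_labels = [l for l, s in zip(labels, spr) if l != "EDF Annotations"]
    data_spr = [s for l, s in zip(labels, spr) if l != "EDF Annotations"]
    if not data_labels:
        raise FormatError(f"{path}: no EEG channels")
    if len(set(data_spr)) > 1:
        offender = data_labels[int(np.argmax(np.asarray(data_spr) != data_spr[0]))]
        raise FormatError(
            f"{path}: mixed sampling rates across channels "
            f"(channel {offender!r} has {data_spr[labels.index(offender)]} "
            f"samples/record, expected {data_spr[0]})"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data(units="uV")
    return Recording(
        channel_labels=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        signal=data_uv,
    )


def _ascii_field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to EDF (16-bit, 1-s data records).

    Requires an integer sampling rate and a whole number of seconds of
    signal. Each channel is scaled to its own physical range so the
    int16 quantisation error stays below ~0.01% of the signal range.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records, rem = divmod(rec.n_samples, fs)
    if rem:
        raise ValueError("EDF writer requires a whole number of seconds of signal")
    ns = len(rec.channel_labels)

    dig_min, dig_max = -32768, 32767
    phys_ranges = []
    digital = np.empty((ns, rec.n_samples), dtype="<i2")
    for i in range(ns):
        x = rec.signal[i]
        amp = max(float(np.max(np.abs(x))), 1e-6)
        # round up to limit header digits
        amp = float(np.format_float_positional(amp * 1.01, precision=6, unique=False))
        phys_ranges.append(amp)
        scaled = np.clip(np.round(x / amp * dig_max), dig_min, dig_max)
        digital[i] = scaled.astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate 01-JAN-2000 X X X", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(str(256 * (1 + ns)), 8),
            _ascii_field("", 44),
            _ascii_field(str(n_records), 8),
            _ascii_field("1", 8),
            _ascii_field(str(ns), 4),
        ]
    )
    var = b"".join(_ascii_field(l, 16) for l in rec.channel_labels)
    var += b"".join(_ascii_field("", 80) for _ in range(ns))
    var += b"".join(_ascii_field("uV", 8) for _ in range(ns))
    var += b"".join(_ascii_field(f"-{a}", 8) for a in phys_ranges)
    var += b"".join(_ascii_field(f"{a}", 8) for a in phys_ranges)
    var += b"".join(_ascii_field(str(dig_min), 8) for _ in range(ns))
    var += b"".join(_ascii_field(str(dig_max), 8) for _ in range(ns))
    var += b"".join(_ascii_field("", 80) for _ in range(ns))
    var += b"".join(_ascii_field(str(fs), 8) for _ in range(ns))
    var += b"".join(_ascii_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(var)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# Hypnograms


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a CSV hypnogram with columns ``epoch_start_s,stage``."""
    df = pd.read_csv(path, comment="#")
    for col in ("epoch_start_s", "stage"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    stages = df["stage"].astype(str).str.strip().to_numpy(dtype=object)
    bad = set(stages) - _VALID_STAGES
    if bad:
        raise FormatError(f"{path}: unknown stage symbols {sorted(bad)}")
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    if len(starts) == 0:
        raise FormatError(f"{path}: empty hypnogram")
    if len(starts) == 1:
        epoch_length = 5.0  # single row: length is unrecoverable; assume 5 s
    else:
        diffs = np.diff(starts)
        if np.max(np.abs(diffs - diffs[0])) > 1e-9:
            raise FormatError(f"{path}: non-uniform epoch spacing")
        epoch_length = float(diffs[0])
    return Hypnogram(epoch_length=epoch_length, labels=stages)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as ``epoch_start_s,stage`` CSV (UTF-8)."""
    starts = np.arange(len(h)) * h.epoch_length
    df = pd.DataFrame({"epoch_start_s": starts, "stage": h.labels})
    df.to_csv(path, index=False)


def expand_hypnogram(h: Hypnogram, target_epoch_length: float = 5.0) -> Hypnogram:
    """Replicate coarse labels onto a finer epoch grid.

    A 30-s hypnogram becomes a 5-s hypnogram by replicating each label 6x;
    total covered time is preserved exactly.
    """
    factor = h.epoch_length / target_epoch_length
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"epoch length {h.epoch_length} not divisible by {target_epoch_length}"
        )
    factor = int(round(factor))
    return Hypnogram(
        epoch_length=target_epoch_length, labels=np.repeat(h.labels, factor)
    )


def hypnogram_agreement(a: Hypnogram, b: Hypnogram) -> dict:
    """Fraction of epochs on which two same-grid hypnograms agree.

    Returns ``{"overall": f, "per_stage": {stage: f or nan}}``. The
    per-stage fraction is conditioned on the stage of ``a`` (among epochs
    `a` calls stage s, how often does `b` agree). UNSCORED epochs in either
    hypnogram are excluded from all denominators.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    la, lb = a.labels, b.labels
    scored = (la != UNSCORED) & (lb != UNSCORED)
    per_stage: dict[str, float] = {}
    for s in STAGES:
        mask = scored & (la == s)
        per_stage[s] = float(np.mean(lb[mask] == s)) if mask.any() else float("nan")
    overall = float(np.mean(la[scored] == lb[scored])) if scored.any() else float("nan")
    return {"overall": overall, "per_stage": per_stage}


def states_per_epoch(h5: Hypnogram, h30: Hypnogram) -> np.ndarray:
    """Distinct 5-s stages inside each 30-s epoch (values in 1..6)."""
    factor = int(round(h30.epoch_length / h5.epoch_length))
    if abs(h30.epoch_length / h5.epoch_length - factor) > 1e-9:
        raise ValueError("epoch lengths not commensurate")
    n30 = len(h5) // factor
    counts = np.empty(n30, dtype=int)
    for i in range(n30):
        counts[i] = len(set(h5.labels[i * factor : (i + 1) * factor]))
    return counts
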