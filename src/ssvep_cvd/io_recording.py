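"""Reading, writing, and epoching of multichannel EEG recordings.

Recordings are small dense matrices (channels x samples, microvolts) with a
per-sample digital trigger marking stimulation (0) versus rest (1) periods.
Two on-disk formats are supported:

* an OpenBCI-GUI-style text dialect: ``%``-prefixed header lines followed by
  comma-separated rows of ``sample_index, <EEG channels...>, trigger``;
* a native tabular format: the same CSV columns without the ``%`` header,
  plus a ``<name>.meta.json`` sidecar carrying fs, channel names and metadata.

All sample coordinates are 0-based and half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

DEFAULT_CHANNELS = ("O1", "O2", "Pz", "Cz")
DEFAULT_FS = 250.0

STIMULATION = "stimulation"
REST = "rest"

#: trigger value -> epoch label (0 = stimulation, 1 = rest)
TRIGGER_LABELS = {0: STIMULATION, 1: REST}


class RecordingFormatError(ValueError):
    """Raised when an on-disk recording violates the expected dialect."""


@dataclass
class Recording:
    """A multichannel EEG recording with a per-sample digital trigger.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    trigger : ndarray of int, shape (n_samples,)
        0 during stimulation, 1 during rest.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        One name per data row, in row order.
    meta : dict
        Free-form metadata (subject id, condition, session id, ...).
    """

    data: np.ndarray
    trigger: np.ndarray
    fs: float = DEFAULT_FS
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.trigger = np.asarray(self.trigger, dtype=int).ravel()
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.data.shape[1] != self.trigger.size:
            raise ValueError(
                f"data has {self.data.shape[1]} samples but trigger has "
                f"{self.trigger.size}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        bad = set(np.unique(self.trigger)) - {0, 1}
        if bad:
            raise ValueError(f"trigger values must be in {{0, 1}}, found {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            trigger=self.trigger.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class Epoch:
    """A half-open run ``[start, end)`` of constant trigger value."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid epoch bounds [{self.start}, {self.end})")
        if self.label not in (STIMULATION, REST):
            raise ValueError(f"unknown epoch label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def read_openbci_txt(path) -> Recording:
    """Read a recording from the OpenBCI-GUI-style text dialect.

    Header lines begin with ``%`` and may carry ``%key = value`` pairs
    (``Sample Rate`` and ``Channels`` are recognized; ``meta.<key>`` entries
    populate :attr:`Recording.meta`). Data rows are comma separated:
    sample index, one column per EEG channel, trigger.
    """
    path = Path(path)
    fs = DEFAULT_FS
    channel_names: tuple[str, ...] | None = None
    meta: dict = {}
    rows: list[list[str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("%"):
                _parse_header_line(line, meta)
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) < 3:
                raise RecordingFormatError(
                    f"{path}:{lineno}: expected at least 3 columns "
                    f"(sample index, >=1 EEG channel, trigger), got {len(fields)}"
                )
            rows.append([str(lineno)] + fields)
    if "sample_rate" in meta:
        fs = float(meta.pop("sample_rate"))
    if "channels" in meta:
        channel_names = tuple(
            c.strip() for c in str(meta.pop("channels")).split(",") if c.strip()
        )
    if not rows:
        raise RecordingFormatError(f"{path}: no data rows")

    n_cols = len(rows[0]) - 1
    data_rows = np.empty((len(rows), n_cols))
    linenos = np.empty(len(rows), dtype=int)
    for i, row in enumerate(rows):
        linenos[i] = int(row[0])
        if len(row) - 1 != n_cols:
            raise RecordingFormatError(
                f"{path}:{row[0]}: ragged row ({len(row) - 1} columns, "
                f"expected {n_cols})"
            )
        try:
            data_rows[i] = [float(v) for v in row[1:]]
        except ValueError as exc:
            raise RecordingFormatError(f"{path}:{row[0]}: unparseable value ({exc})")

    idx = data_rows[:, 0]
    if np.any(np.diff(idx) <= 0):
        bad = int(np.argmax(np.diff(idx) <= 0)) + 1
        raise RecordingFormatError(
            f"{path}:{linenos[bad]}: non-monotone sample index"
        )
    trig = data_rows[:, -1]
    bad_trig = (trig != 0) & (trig != 1)
    if np.any(bad_trig):
        bad = int(np.argmax(bad_trig))
        raise RecordingFormatError(
            f"{path}:{linenos[bad]}: trigger value {trig[bad]!r} not in {{0, 1}}"
        )
    eeg = data_rows[:, 1:-1].T
    if eeg.shape[0] < 1:
        raise RecordingFormatError(f"{path}: no EEG columns")
    if channel_names is None:
        channel_names = (
            DEFAULT_CHANNELS
            if eeg.shape[0] == len(DEFAULT_CHANNELS)
            else tuple(f"ch{i + 1}" for i in range(eeg.shape[0]))
        )
    return Recording(
        data=eeg,
        trigger=trig.astype(int),
        fs=fs,
        channel_names=channel_names,
        meta=meta,
    )


def _parse_header_line(line: str, meta: dict) -> None:
    body = line.lstrip("%").strip()
    if "=" not in body:
        return
    key, _, value = body.partition("=")
    key = key.strip().lower().replace(" ", "_")
    value = value.strip()
    if key == "sample_rate":
        meta["sample_rate"] = value.split()[0]  # tolerate trailing "Hz"
    elif key == "channels":
        meta["channels"] = value
    elif key.startswith("meta."):
        meta[key[len("meta."):]] = value


def write_recording(rec: Recording, path) -> Path:
    """Write *rec* in the OpenBCI-style dialect read by :func:`read_openbci_txt`.

    Values are written with enough digits (%.9g) to round-trip within 1e-6
    relative; the trigger is written exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("%OpenBCI-style EEG export\n")
        fh.write(f"%Sample Rate = {rec.fs:g} Hz\n")
        fh.write(f"%Channels = {','.join(rec.channel_names)}\n")
        for key, value in rec.meta.items():
            fh.write(f"%meta.{key} = {value}\n")
        for i in range(rec.n_samples):
            vals = ",".join(f"{v:.9g}" for v in rec.data[:, i])
            fh.write(f"{i},{vals},{rec.trigger[i]}\n")
    return path


def write_native(rec: Recording, path) -> Path:
    """Write the native CSV + ``<name>.meta.json`` sidecar pair."""
    path = Path(path)
    header = "sample," + ",".join(rec.channel_names) + ",trigger"
    table = np.column_stack(
        [np.arange(rec.n_samples), rec.data.T, rec.trigger]
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for row in table:
            fh.write(
                f"{int(row[0])},"
                + ",".join(f"{v:.9g}" for v in row[1:-1])
                + f",{int(row[-1])}\n"
            )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "fs": rec.fs,
                "channel_names": list(rec.channel_names),
                "meta": rec.meta,
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    return path


def read_native(path) -> Recording:
    """Read a recording written by :func:`write_native`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        table = np.loadtxt(fh, delimiter=",", ndmin=2)
    if header[0] != "sample" or header[-1] != "trigger":
        raise RecordingFormatError(
            f"{path}:1: expected 'sample,...,trigger' header, got {header!r}"
        )
    channel_names = tuple(header[1:-1])
    fs = DEFAULT_FS
    meta: dict = {}
    if sidecar.exists():
        side = json.loads(sidecar.read_text(encoding="utf-8"))
        fs = float(side.get("fs", fs))
        channel_names = tuple(side.get("channel_names", channel_names))
        meta = dict(side.get("meta", {}))
    return Recording(
        data=table[:, 1:-1].T,
        trigger=table[:, -1].astype(int),
        fs=fs,
        channel_names=channel_names,
        meta=meta,
    )


def epochs_from_trigger(rec: Recording, min_epoch_samples: int = 0) -> list[Epoch]:
    """Decode the trigger into maximal constant-value runs.

    Runs of trigger value 0 become stimulation epochs, runs of 1 rest
    epochs. Epochs tile ``[0, n_samples)`` with no gaps or overlaps;
    epochs shorter than *min_epoch_samples* are dropped (glitch filtering
    is an explicit opt-in, not a default).
    """
    trig = rec.trigger
    if trig.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(trig)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [trig.size]))
    epochs = [
        Epoch(int(s), int(e), TRIGGER_LABELS[int(trig[s])])
        for s, e in zip(starts, ends)
        if (e - s) >= min_epoch_samples
    ]
    return epochs
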