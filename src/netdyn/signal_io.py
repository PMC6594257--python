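"""Multichannel LFP/EEG recording I/O and epoching.

Recordings are continuous voltage traces (microvolts) from a fixed set of
named depth electrodes sampled at a constant rate.  Two on-disk formats are
supported:

* delimited text — comma-separated samples with one header row of channel
  labels and a leading ``# fs=<Hz> ...`` sidecar comment line; lossless and
  trivially inspectable, used for fixtures and cohort output;
* EDF (European Data Format) — 16-bit integer encoding against a per-channel
  physical range, the field's standard interchange format.  Reading goes
  through :mod:`mne`; writing uses a minimal EDF+ compliant encoder because
  no installed library writes EDF.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MultichannelRecording",
    "EpochSet",
    "read_recording",
    "write_recording",
    "slice_epochs",
]


@dataclass
class MultichannelRecording:
    """Continuous samples × named channels at a fixed sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Voltage samples in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Ordered, unique channel labels.  All downstream addressing is by
        label, never by position.
    meta : dict
        Free-form metadata (animal id, group, week, ...).
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channels = [str(c) for c in self.channels]
        if len(self.channels) < 1:
            raise ValueError("need at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channel labels: {self.channels}")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channels)} channel labels"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite sample at row {i}, channel {self.channels[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording (have {self.channels})"
            ) from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[:, self.channel_index(label)]

    def subset(self, labels: list[str]) -> "MultichannelRecording":
        """Recording restricted to ``labels`` (in the given order)."""
        idx = [self.channel_index(c) for c in labels]
        return MultichannelRecording(
            self.data[:, idx], self.fs, list(labels), dict(self.meta)
        )


@dataclass
class EpochSet:
    """Equal-length analysis windows cut from a recording.

    ``epochs`` has shape (n_epochs, epoch_len, n_channels).
    """

    epochs: np.ndarray
    fs: float
    channels: list[str]
    epoch_len_s: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, epoch_len, n_channels)")
        n = self.epoch_len_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_len_s × fs must be an integer")
        if self.epochs.shape[1] != round(n):
            raise ValueError("epoch length inconsistent with epoch_len_s × fs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def epoch_recording(self, i: int) -> MultichannelRecording:
        """Epoch ``i`` wrapped back into a recording."""
        return MultichannelRecording(self.epochs[i], self.fs, list(self.channels))


# ---------------------------------------------------------------------------
# Delimited text format
# ---------------------------------------------------------------------------

def _write_delimited(rec: MultichannelRecording, path: Path) -> None:
    meta_items = " ".join(
        f"{k}={v}" for k, v in rec.meta.items() if " " not in f"{k}{v}"
    )
    header = f"# fs={rec.fs:.10g}"
    if meta_items:
        header += " " + meta_items
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write(",".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data, fmt="%.17g", delimiter=",")


def _read_delimited(path: Path) -> MultichannelRecording:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise ValueError(
                f"{path}: delimited recordings need a leading '# fs=<Hz>' line"
            )
        fields = first.lstrip("# ").split()
        meta: dict = {}
        fs = None
        for item in fields:
            if "=" not in item:
                continue
            k, v = item.split("=", 1)
            if k == "fs":
                fs = float(v)
            else:
                meta[k] = v
        if fs is None:
            raise ValueError(f"{path}: sidecar line does not state fs")
        header = fh.readline().strip()
        channels = [c.strip() for c in header.split(",")]
        if any(not c for c in channels):
            raise ValueError(f"{path}: empty channel label in header")
        if len(set(channels)) != len(channels):
            raise ValueError(f"{path}: duplicate channel labels {channels}")
        body = fh.read()
    frame = pd.read_csv(
        io.StringIO(body), header=None, names=channels,
        float_precision="round_trip",
    )
    data = frame.to_numpy(dtype=np.float64)
    if data.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    bad = ~np.isfinite(data)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-finite sample at row {i}, channel {channels[j]!r}"
        )
    return MultichannelRecording(data, fs, channels, meta)


# ---------------------------------------------------------------------------
# EDF (16-bit European Data Format)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: MultichannelRecording, path: Path) -> None:
    """Minimal EDF writer: 1-s data records, 16-bit samples, µV units.

    Requires an integer sampling rate and a whole number of seconds of data
    (pad or trim beforehand); both are inherent to the fixed-record layout.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records, rem = divmod(rec.n_samples, fs)
    if rem or n_records == 0:
        raise ValueError(
            "EDF writer requires a whole number of seconds of data "
            f"(got {rec.n_samples} samples at fs={fs})"
        )
    ns = rec.n_channels
    # physical range per channel, symmetric, padded so extremes stay in range
    absmax = np.max(np.abs(rec.data), axis=0)
    absmax = np.where(absmax > 0, absmax * (1 + 1e-6), 1.0)
    dig_min, dig_max = -32767, 32767

    now = _dt.datetime(2000, 1, 1)
    head = b""
    head += _edf_field("0", 8)
    pid = rec.meta.get("animal", "X")
    head += _edf_field(f"{pid} netdyn", 80)
    head += _edf_field(
        " ".join(f"{k}={v}" for k, v in rec.meta.items())[:80] or "netdyn", 80
    )
    head += _edf_field(now.strftime("%d.%m.%y"), 8)
    head += _edf_field(now.strftime("%H.%M.%S"), 8)
    head += _edf_field(256 * (ns + 1), 8)
    head += _edf_field("", 44)
    head += _edf_field(n_records, 8)
    head += _edf_field(1, 8)
    head += _edf_field(ns, 4)

    for vals, width in (
        (rec.channels, 16),
        (["AgAgCl electrode"] * ns, 80),
        (["uV"] * ns, 8),
        ([f"{-m:.8g}"[:8] for m in absmax], 8),
        ([f"{m:.8g}"[:8] for m in absmax], 8),
        ([dig_min] * ns, 8),
        ([dig_max] * ns, 8),
        ([""] * ns, 80),
        ([fs] * ns, 8),
        ([""] * ns, 32),
    ):
        for v in vals:
            head += _edf_field(v, width)

    scale = (dig_max - dig_min) / (2 * absmax)  # digital units per µV
    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_records):
            block = rec.data[r * fs : (r + 1) * fs]  # (fs, ns)
            dig = np.rint((block + absmax) * scale + dig_min).astype("<i2")
            fh.write(dig.T.tobytes())  # channel-major within a record


def _read_edf(path: Path) -> MultichannelRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is a declared extra
        raise ImportError(
            "reading EDF requires the 'mne' package (pip install netdyn[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # mne returns volts; recordings are µV
    channels = list(raw.ch_names)
    rec = MultichannelRecording(data, float(raw.info["sfreq"]), channels)
    return rec


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

_FORMATS = ("edf", "delimited")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt", ".tsv"):
        return "delimited"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_recording(path, format: str | None = None) -> MultichannelRecording:
    """Read a multichannel recording from ``path``.

    Parameters
    ----------
    path : path-like
    format : {'edf', 'delimited'}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    return _read_delimited(path)


def write_recording(rec: MultichannelRecording, path, format: str | None = None) -> None:
    """Write ``rec`` to ``path``.

    Delimited output round-trips bit-identically; EDF quantizes each channel
    to 16 bits over its symmetric physical range (max error < range/2^16).
    """
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    path = Path(path)
    fmt = _infer_format(path, format)
    parent = path.parent
    if parent and not parent.exists():
        raise IOError(f"directory {parent} does not exist")
    if fmt == "edf":
        _write_edf(rec, path)
    else:
        _write_delimited(rec, path)


def slice_epochs(
    rec: MultichannelRecording, epoch_len_s: float, step_s: float | None = None
) -> EpochSet:
    """Cut a recording into equal-length epochs.

    ``n_epochs = floor((n_samples − epoch_len) / step) + 1``; the default
    step equals the epoch length (non-overlapping windows).
    """
    if step_s is None:
        step_s = epoch_len_s
    n_len = epoch_len_s * rec.fs
    if abs(n_len - round(n_len)) > 1e-9:
        raise ValueError("epoch_len_s × fs must be an integer number of samples")
    n_len = int(round(n_len))
    if n_len < 1:
        raise ValueError("epoch length must be at least one sample")
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    step = max(1, int(round(step_s * rec.fs)))
    if rec.n_samples < n_len:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"epoch ({n_len} samples)"
        )
    n_epochs = (rec.n_samples - n_len) // step + 1
    starts = np.arange(n_epochs) * step
    epochs = np.stack([rec.data[s : s + n_len] for s in starts])
    return EpochSet(epochs, rec.fs, list(rec.channels), epoch_len_s)
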