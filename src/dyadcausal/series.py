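"""Sampled multichannel signal blocks and the plain-text I/O around them.

The :class:`MultichannelSeries` is the unit every pipeline stage consumes and
produces: a T x N matrix of samples with channel labels, a sampling rate and a
segment start time.  Series are exchanged on disk as delimited numeric matrices
with a single header row of channel labels (tab or comma separated); tap trains
as one timestamp in seconds per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import TapParseError

__all__ = [
    "MultichannelSeries",
    "TaskEvent",
    "read_series",
    "write_series",
    "read_events",
    "read_taps",
    "write_taps",
    "read_edf",
]


@dataclass
class MultichannelSeries:
    """A T x N sampled signal block.

    Parameters
    ----------
    values : ndarray of shape (T, N)
        Signal samples, one column per channel.  Must be finite: the causal
        analysis assumes series without missing values.
    labels : list of str
        Unique channel labels, one per column.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Start time of the block in seconds (segment onset).
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)
    fs: float = 1.0
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (T, N) array")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.values.shape[1])]
        self.labels = [str(s) for s in self.labels]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[1]} columns"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("series contains non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Length of the block in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_values(self, values, *, fs=None, labels=None, t0=None) -> "MultichannelSeries":
        return MultichannelSeries(
            values=np.asarray(values, dtype=float),
            labels=list(self.labels if labels is None else labels),
            fs=self.fs if fs is None else fs,
            t0=self.t0 if t0 is None else t0,
        )

    def copy(self) -> "MultichannelSeries":
        return replace(self, values=self.values.copy(), labels=list(self.labels))


@dataclass(frozen=True)
class TaskEvent:
    """One task window, e.g. ``lead``/``follow``/``alone``/``rest``."""

    label: str
    onset: float
    offset: float

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValueError(
                f"event {self.label!r}: offset {self.offset} must exceed onset {self.onset}"
            )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_series(path, fs: float, *, t0: float = 0.0, delimiter: str | None = None) -> MultichannelSeries:
    """Read a delimited numeric matrix with one header row of channel labels."""
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delimiter)
    return MultichannelSeries(
        values=frame.to_numpy(dtype=float), labels=list(frame.columns), fs=fs, t0=t0
    )


def write_series(series: MultichannelSeries, path, *, delimiter: str = "\t") -> None:
    frame = pd.DataFrame(series.values, columns=series.labels)
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def read_events(path, *, delimiter: str | None = None) -> list[TaskEvent]:
    """Read task events from a delimited file with columns label, onset, offset."""
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=delimiter)
    cols = {c.lower(): c for c in frame.columns}
    for need in ("label", "onset", "offset"):
        if need not in cols:
            raise KeyError(f"events file {path} lacks column {need!r}")
    return [
        TaskEvent(str(row[cols["label"]]), float(row[cols["onset"]]), float(row[cols["offset"]]))
        for _, row in frame.iterrows()
    ]


def read_taps(path) -> np.ndarray:
    """Read a tap train: one timestamp (seconds) per line; blank lines ignored."""
    times = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                times.append(float(line))
            except ValueError:
                raise TapParseError(path, lineno, line) from None
    return np.asarray(times, dtype=float)


def write_taps(times, path) -> None:
    with open(path, "w") as fh:
        for t in np.asarray(times, dtype=float):
            fh.write(f"{t:.6f}\n")


def read_edf(path, *, channels: list[str] | None = None) -> MultichannelSeries:
    """Read an EDF/BDF biosignal file into a :class:`MultichannelSeries`.

    Requires the optional ``mne`` dependency (``pip install dyadcausal[edf]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF/BDF reading requires the optional 'mne' dependency") from exc
    suffix = Path(path).suffix.lower()
    reader = mne.io.read_raw_bdf if suffix == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    return MultichannelSeries(
        values=raw.get_data().T, labels=list(raw.ch_names), fs=float(raw.info["sfreq"])
    )
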