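"""Containers and file I/O for multichannel EEG recordings.

A :class:`Recording` holds a sample-major (time x channel) matrix in
microvolts together with the sampling rate, channel labels and optional
trial-onset markers.  Trials are cut out of a recording relative to those
markers into a :class:`TrialSet`, the unit of data every downstream stage
(artifact removal, time-frequency features, detector training) consumes.

Supported on-disk formats are a human-inspectable CSV dialect and HDF5;
EDF reading is available when an EDF backend (``mne`` or ``pyedflib``) is
installed.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Recording",
    "TrialSet",
    "load_recording",
    "save_recording",
    "extract_trials",
    "save_trialset",
    "load_trialset",
]


class FormatError(ValueError):
    """A file does not conform to the declared on-disk format."""


@dataclass
class Recording:
    """Multichannel EEG time series.

    Parameters
    ----------
    data:
        ``(n_samples, n_channels)`` float matrix, microvolts.
    fs:
        Sampling rate in Hz (256 Hz is the conventional default for the
        mental-task protocol this package targets).
    channel_labels:
        10-20-system electrode names, one per column of ``data``.
    markers:
        Optional list of ``(sample_index, class_id)`` trial-onset events.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    markers: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_samples, n_channels) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[1]} data columns"
            )
        if not np.isfinite(self.data).all():
            raise FormatError("recording contains non-finite samples")
        if self.markers is not None:
            self.markers = [(int(s), int(c)) for s, c in self.markers]
            for s, _ in self.markers:
                if not 0 <= s < self.n_samples:
                    raise ValueError(f"marker sample index {s} out of range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class TrialSet:
    """Fixed-length labeled trial segments cut from one or more recordings.

    ``trials`` is a list of ``(segment, class_id)`` pairs where every
    segment is a ``(window_samples, n_channels)`` array.  Class ids are
    integers in ``1..n_classes``.
    """

    trials: list[tuple[np.ndarray, int]]
    fs: float
    window: tuple[float, float] = (0.0, 0.0)  # (start offset s, duration s)

    def __post_init__(self) -> None:
        if self.trials:
            shape = self.trials[0][0].shape
            for seg, _ in self.trials:
                if seg.shape != shape:
                    raise ValueError("all trial segments must share one shape")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c for _, c in self.trials], dtype=int)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def X(self) -> np.ndarray:
        """Trials stacked into an ``(n_trials, window_samples, n_channels)`` array."""
        return np.stack([seg for seg, _ in self.trials])

    def subset(self, indices) -> "TrialSet":
        return TrialSet([self.trials[i] for i in indices], self.fs, self.window)


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    return {
        ".csv": "csv",
        ".h5": "hdf5",
        ".hdf5": "hdf5",
        ".edf": "edf",
    }.get(ext, "csv")


def load_recording(path: str, format: str | None = None) -> Recording:
    """Read a :class:`Recording` from CSV, HDF5 or (optionally) EDF.

    The CSV dialect is one ``# fs=<Hz>`` comment line, an optional
    ``# markers=<sample>:<class>;...`` comment line, a channel-label header
    row, then one sample per row.
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "csv":
        return _load_csv(path)
    if fmt == "hdf5":
        return _load_hdf5(path)
    if fmt == "edf":
        return _load_edf(path)
    raise ValueError(f"unknown format {fmt!r}")


def save_recording(rec: Recording, path: str, format: str | None = None) -> None:
    """Write a recording; HDF5 round-trips at float64 precision, CSV at 6 decimals."""
    if rec.n_samples == 0:
        raise ValueError("refusing to save an empty recording")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _save_csv(rec, path)
    elif fmt == "hdf5":
        _save_hdf5(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _load_csv(path: str) -> Recording:
    fs = None
    markers = None
    body_lines = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                content = stripped.lstrip("#").strip()
                if content.startswith("fs="):
                    fs = float(content[3:])
                elif content.startswith("markers="):
                    spec = content[len("markers="):]
                    markers = []
                    for item in spec.split(";"):
                        if item:
                            s, c = item.split(":")
                            markers.append((int(s), int(c)))
            elif stripped:
                body_lines.append(line)
    if fs is None:
        raise FormatError("CSV is missing the required '# fs=<Hz>' metadata line")
    frame = pd.read_csv(_io.StringIO("".join(body_lines)))
    data = frame.to_numpy(dtype=np.float64)
    if not np.isfinite(data).all():
        raise FormatError("CSV contains NaN or infinite samples")
    return Recording(data, fs, [str(c) for c in frame.columns], markers)


def _save_csv(rec: Recording, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        if rec.markers:
            spec = ";".join(f"{s}:{c}" for s, c in rec.markers)
            fh.write(f"# markers={spec}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data, fmt="%.6f", delimiter=",")


def _load_hdf5(path: str) -> Recording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError("HDF5 recording is missing the 'data' dataset")
        if "fs" not in f.attrs:
            raise FormatError("HDF5 recording is missing the 'fs' attribute")
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        labels = [l.decode() if isinstance(l, bytes) else str(l)
                  for l in f["channel_labels"][()]]
        markers = None
        if "markers" in f:
            markers = [(int(s), int(c)) for s, c in f["markers"][()]]
    return Recording(data, fs, labels, markers)


def _save_hdf5(rec: Recording, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.create_dataset(
            "channel_labels",
            data=np.array(rec.channel_labels, dtype=h5py.string_dtype()),
        )
        if rec.markers:
            f.create_dataset("markers", data=np.array(rec.markers, dtype=np.int64))


def _load_edf(path: str) -> Recording:
    """EDF reading is optional: it requires mne or pyedflib."""
    try:
        import mne  # type: ignore

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data().T * 1e6  # mne works in volts
        return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    except ImportError:
        pass
    try:
        import pyedflib  # type: ignore

        with pyedflib.EdfReader(path) as f:
            sigs = np.column_stack([f.readSignal(i) for i in range(f.signals_in_file)])
            labels = f.getSignalLabels()
            fs = float(f.getSampleFrequency(0))
        return Recording(sigs, fs, list(labels))
    except ImportError as exc:
        raise ImportError(
            "EDF support requires the optional 'mne' or 'pyedflib' package"
        ) from exc


def extract_trials(rec: Recording, window_start: float, window_len: float) -> TrialSet:
    """Cut one fixed-length trial per marker.

    Trial ``i`` covers samples ``[m_i + round(window_start*fs),
    m_i + round((window_start + window_len)*fs))`` — half-open, 0-based —
    where ``m_i`` is the i-th marker sample.  The defaults used throughout
    the package (start 3 s, length 7 s) select the imagery period of the
    10-s cue-based protocol.
    """
    if not rec.markers:
        raise ValueError("recording has no trial markers")
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    offset = int(round(window_start * rec.fs))
    n_win = int(round(window_len * rec.fs))
    trials = []
    for m, class_id in rec.markers:
        start = m + offset
        stop = start + n_win
        if start < 0 or stop > rec.n_samples:
            raise ValueError(
                f"window [{start}, {stop}) for marker at sample {m} exceeds "
                f"recording bounds [0, {rec.n_samples})"
            )
        trials.append((rec.data[start:stop].copy(), class_id))
    return TrialSet(trials, rec.fs, (window_start, window_len))


def save_trialset(ts: TrialSet, path: str) -> None:
    """HDF5 layout: /trials (T, N, C), /labels (T,), attrs fs and window."""
    if not ts.trials:
        raise ValueError("refusing to save an empty trial set")
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=ts.X)
        f.create_dataset("labels", data=ts.labels)
        f.attrs["fs"] = ts.fs
        f.attrs["window"] = list(ts.window)


def load_trialset(path: str) -> TrialSet:
    with h5py.File(path, "r") as f:
        X = f["trials"][()]
        y = f["labels"][()]
        fs = float(f.attrs["fs"])
        window = tuple(f.attrs.get("window", (0.0, 0.0)))
    return TrialSet([(X[i], int(y[i])) for i in range(len(y))], fs, window)
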