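"""Recording I/O, transition trimming and sliding-window segmentation.

Readers cover two layouts:

* delimited text — one row per time step, ``n_channels`` numeric columns,
  whitespace- or comma-separated (auto-detected), with an optional
  ``labels.tsv`` sidecar mapping file names to gesture labels;
* multi-armband MAT containers (v5 and v7.3/HDF5) holding an ``emg``
  matrix and a per-sample ``stimulus`` label vector, segmented into one
  recording per contiguous constant-label run.

Window indexing is 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "WindowSample",
    "ParseError",
    "FormatError",
    "read_delimited_recording",
    "read_recording_dir",
    "write_recording_dir",
    "read_ninapro_db5",
    "trim_transitions",
    "segment_windows",
    "window_count",
]

DEFAULT_WINDOW_LENGTH = 52  # 260 ms at 200 Hz
DEFAULT_STRIDE = 5  # 25 ms at 200 Hz; the source protocol leaves this open


class ParseError(ValueError):
    """Malformed delimited-text recording."""


class FormatError(ValueError):
    """MAT container missing a required field."""


@dataclass(frozen=True)
class Recording:
    """A labelled contiguous multi-channel raw sEMG segment."""

    signal: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    gesture_label: object
    subject_id: str = ""

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[0] < 1 or sig.shape[1] < 1:
            raise ValueError(f"signal must be (channels, samples), got {sig.shape}")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "signal", sig)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class WindowSample:
    """One fixed-length analysis window cut from a recording."""

    window: np.ndarray  # (n_channels, window_length)
    gesture_label: object
    source: tuple[str, int] = ("", 0)  # (subject_id, start index, 0-based)

    def __post_init__(self):
        win = np.asarray(self.window, dtype=float)
        if win.ndim != 2:
            raise ValueError("window must be 2-D (channels, samples)")
        if not np.all(np.isfinite(win)):
            raise ValueError("window contains non-finite values")
        object.__setattr__(self, "window", win)


def read_delimited_recording(
    path,
    n_channels: int,
    sample_rate: float,
    gesture_label,
    subject_id: str = "",
) -> Recording:
    """Parse a delimited-text recording (rows = time steps).

    The delimiter is auto-detected: comma if the first data line contains
    one, otherwise any whitespace.  Ragged or non-numeric rows raise
    :class:`ParseError` naming the 1-based line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    delimiter = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                delimiter = "," if "," in line else None if line else None
                delimiter = "," if "," in line else "ws"
            fields = line.split(",") if delimiter == "," else line.split()
            if len(fields) != n_channels:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_channels} fields, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: empty recording file")
    signal = np.asarray(rows, dtype=float).T  # rows are time steps
    return Recording(signal, sample_rate, gesture_label, subject_id)


def write_recording_dir(recordings, directory) -> None:
    """Write recordings as whitespace-delimited text plus a labels.tsv sidecar.

    Layout readable by :func:`read_recording_dir`; one file per recording,
    one row per time step.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["filename\tgesture_label\tsubject_id\tsample_rate"]
    for i, rec in enumerate(recordings):
        name = f"rec_{i:05d}.txt"
        np.savetxt(directory / name, rec.signal.T, fmt="%.10g")
        lines.append(
            f"{name}\t{rec.gesture_label}\t{rec.subject_id}\t{rec.sample_rate:g}"
        )
    (directory / "labels.tsv").write_text("\n".join(lines) + "\n")


def read_recording_dir(directory) -> list[Recording]:
    """Read back a directory written by :func:`write_recording_dir`."""
    directory = Path(directory)
    sidecar = directory / "labels.tsv"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    recordings = []
    lines = sidecar.read_text().strip().splitlines()
    for line in lines[1:]:
        name, label, subject, rate = line.split("\t")
        data = np.loadtxt(directory / name, ndmin=2)
        recordings.append(
            Recording(data.T, float(rate), _parse_label(label), subject)
        )
    return recordings


def _parse_label(text: str):
    try:
        return int(text)
    except ValueError:
        return text


def read_ninapro_db5(
    path,
    armband: str = "first",
    use_refined_labels: bool = False,
    sample_rate: float = 200.0,
) -> list[Recording]:
    """Load a two-armband MAT recording and split it by gesture runs.

    The container must hold a per-sample ``emg`` matrix (16 columns, two
    8-channel armbands) and a ``stimulus`` label vector (``restimulus``
    when ``use_refined_labels``).  Only the selected armband's 8 channels
    are kept: ``first`` keeps columns 1-8, ``second`` columns 9-16
    (1-based).  Each contiguous constant-label run becomes one
    :class:`Recording`; label 0 is the neutral gesture.
    """
    if armband not in ("first", "second"):
        raise ValueError(f"armband must be 'first' or 'second', got {armband!r}")
    label_field = "restimulus" if use_refined_labels else "stimulus"
    arrays = _load_mat(path)
    if "emg" not in arrays:
        raise FormatError(f"{path}: missing required field 'emg'")
    if label_field not in arrays:
        raise FormatError(f"{path}: missing required field {label_field!r}")
    emg = np.atleast_2d(np.asarray(arrays["emg"], dtype=float))
    labels = np.asarray(arrays[label_field]).ravel().astype(int)
    if emg.shape[0] != labels.size and emg.shape[1] == labels.size:
        emg = emg.T  # v7.3/HDF5 files store matrices transposed
    if emg.shape[0] != labels.size:
        raise FormatError(
            f"{path}: emg has {emg.shape[0]} samples but {label_field} "
            f"has {labels.size}"
        )
    if armband == "second" and emg.shape[1] < 16:
        raise ValueError(
            f"armband='second' requires >= 16 channels, file has {emg.shape[1]}"
        )
    cols = slice(0, 8) if armband == "first" else slice(8, 16)
    emg = emg[:, cols]
    subject = str(int(np.asarray(arrays.get("subject", 0)).ravel()[0]))
    recordings = []
    for start, stop, label in _constant_runs(labels):
        recordings.append(
            Recording(emg[start:stop].T, sample_rate, int(label), subject)
        )
    return recordings


def _constant_runs(labels: np.ndarray):
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [labels.size]])
    for start, stop in zip(starts, stops):
        yield int(start), int(stop), labels[start]


def _load_mat(path) -> dict:
    """Read MAT v5 via scipy, v7.3 via h5py."""
    from scipy.io import loadmat

    try:
        raw = loadmat(path)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        import h5py

        out = {}
        with h5py.File(path, "r") as fh:
            for key in fh:
                out[key] = np.asarray(fh[key])
        return out


def trim_transitions(recording: Recording, trim_ms: float) -> Recording:
    """Drop ``round(trim_ms * rate / 1000)`` samples from each end."""
    if trim_ms < 0:
        raise ValueError("trim_ms must be >= 0")
    k = int(round(trim_ms * recording.sample_rate / 1000.0))
    if k == 0:
        return recording
    if 2 * k >= recording.n_samples:
        raise ValueError(
            f"trimming {k} samples from each end would empty a "
            f"{recording.n_samples}-sample recording"
        )
    return Recording(
        recording.signal[:, k : recording.n_samples - k],
        recording.sample_rate,
        recording.gesture_label,
        recording.subject_id,
    )


def window_count(n_samples: int, window_length: int, stride: int) -> int:
    """Closed-form number of complete windows."""
    if n_samples < window_length:
        return 0
    return (n_samples - window_length) // stride + 1


def segment_windows(
    recording: Recording,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    stride: int = DEFAULT_STRIDE,
) -> list[WindowSample]:
    """Cut complete windows at starts 0, stride, 2*stride, ...

    The incomplete tail is dropped; a recording shorter than one window
    yields an empty list.
    """
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    out = []
    for start in range(
        0, recording.n_samples - window_length + 1, stride
    ):
        out.append(
            WindowSample(
                window=recording.signal[:, start : start + window_length].copy(),
                gesture_label=recording.gesture_label,
                source=(recording.subject_id, start),
            )
        )
    assert len(out) == window_count(recording.n_samples, window_length, stride)
    return out
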