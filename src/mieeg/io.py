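"""Reading, writing and epoching of multichannel EEG recordings.

The on-disk formats are deliberately plain: CSV (one column per channel,
header row of channel names, events in a two-column sidecar table) and
16-bit EDF.  Epoched trials travel in a single HDF5 container with
datasets ``/trials``, ``/labels`` and ``/fs``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 14 measurement electrodes of the portable acquisition headset,
#: 10-20 system, in device order.
DEFAULT_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Prefrontal channels used to screen ocular-artifact ICA components.
FRONTAL_CHANNELS = ("AF3", "AF4", "F7", "F8")


class FormatError(ValueError):
    """Raised when a file does not conform to the expected EEG format."""


@dataclass
class RawRecording:
    """A multichannel scalp EEG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Scalp potentials in microvolts.
    channel_names : list of str
        Electrode labels (10-20 system), one per row of ``samples``.
    fs : float
        Sampling rate in Hz.
    events : list of (int, int)
        ``(onset_sample, class_id)`` trial annotations; class ids are 1-6.
    """

    samples: np.ndarray
    channel_names: list[str]
    fs: float
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} rows"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    def copy_with(self, samples: np.ndarray) -> "RawRecording":
        """Return a new recording with the same metadata but new samples."""
        return RawRecording(
            samples=np.asarray(samples, dtype=float),
            channel_names=list(self.channel_names),
            fs=self.fs,
            events=list(self.events),
        )


@dataclass
class TrialSet:
    """Epoched trials sharing one window relative to the cue.

    ``trials`` is a (n_trials, n_channels, n_samples) stack, ``labels``
    the per-trial class ids, and ``window`` the epoch limits in seconds.
    """

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, n_channels, n_samples)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("one label per trial required")

    def __len__(self) -> int:
        return self.trials.shape[0]


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _events_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".events.csv")


def write_csv(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as CSV (header = channel names, one column each).

    Events go to a two-column sidecar ``<path>.events.csv`` with columns
    ``sample`` and ``class``; the sampling rate is recorded in a comment
    on the first line.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        fh.write(",".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.samples.T, delimiter=",", fmt="%.6f")
    if rec.events:
        ev = pd.DataFrame(rec.events, columns=["sample", "class"])
        ev.to_csv(_events_sidecar(path), index=False)


def _read_csv(path: Path) -> RawRecording:
    with open(path) as fh:
        first = fh.readline().strip()
    fs = None
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first.lstrip("#").replace(";", " ").split():
            if tok.startswith("fs="):
                fs = float(tok[3:])
    if fs is None:
        raise FormatError(f"{path}: no sampling rate ('# fs=...' line) found")
    frame = pd.read_csv(path, skiprows=skip)
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no channels found")
    events: list[tuple[int, int]] = []
    sidecar = _events_sidecar(path)
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        events = [(int(s), int(c)) for s, c in zip(ev["sample"], ev["class"])]
    return RawRecording(
        samples=frame.to_numpy().T,
        channel_names=[str(c) for c in frame.columns],
        fs=fs,
        events=events,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as a plain 16-bit EDF file.

    One data record per second; the signal length is zero-padded to a
    whole number of records.  Physical units are microvolts.  Events are
    written to the CSV sidecar (plain EDF carries no annotation track).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_times / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : rec.n_times] = rec.samples

    # per-channel physical range, padded so the range is never degenerate
    pmin = np.floor(data.min(axis=1)) - 1.0
    pmax = np.ceil(data.max(axis=1)) + 1.0
    dmin, dmax = -32768, 32767

    def a(text: str, width: int) -> bytes:
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        a("0", 8),
        a("X X X X", 80),            # patient id
        a("Startdate X X X X", 80),  # recording id
        a("01.01.00", 8),
        a("00.00.00", 8),
        a(str(256 * (1 + n_ch)), 8),
        a("", 44),
        a(str(n_rec), 8),
        a("1", 8),                   # record duration, seconds
        a(str(n_ch), 4),
    ])
    header += b"".join(a(lbl, 16) for lbl in rec.channel_names)
    header += b"".join(a("AgAgCl electrode", 80) for _ in range(n_ch))
    header += b"".join(a("uV", 8) for _ in range(n_ch))
    header += b"".join(a(f"{v:g}", 8) for v in pmin)
    header += b"".join(a(f"{v:g}", 8) for v in pmax)
    header += b"".join(a(str(dmin), 8) for _ in range(n_ch))
    header += b"".join(a(str(dmax), 8) for _ in range(n_ch))
    header += b"".join(a("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(a(str(fs), 8) for _ in range(n_ch))
    header += b"".join(a("", 32) for _ in range(n_ch))

    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    if rec.events:
        ev = pd.DataFrame(rec.events, columns=["sample", "class"])
        ev.to_csv(_events_sidecar(path), index=False)


def _read_edf(path: Path) -> RawRecording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne returns Volts for uV-typed channels
    events: list[tuple[int, int]] = []
    sidecar = _events_sidecar(path)
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        events = [(int(s), int(c)) for s, c in zip(ev["sample"], ev["class"])]
    else:
        for onset, _, desc in zip(*_edf_annotations(raw)):
            try:
                events.append((int(round(onset * raw.info["sfreq"])), int(desc)))
            except ValueError:
                continue
    return RawRecording(
        samples=samples,
        channel_names=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        events=events,
    )


def _edf_annotations(raw) -> tuple[list, list, list]:
    ann = raw.annotations
    return list(ann.onset), list(ann.duration), list(ann.description)


def read_raw_eeg(path: str | Path, format: str | None = None) -> RawRecording:
    """Read a raw EEG file in EDF or CSV form.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"edf", "csv"}, optional
        Forced format; inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        return _read_csv(path)
    if format == "edf":
        return _read_edf(path)
    raise FormatError(f"unsupported format {format!r} (expected 'edf' or 'csv')")


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_trials(
    rec: RawRecording, window: tuple[float, float] = (0.0, 5.0)
) -> TrialSet:
    """Cut event-locked trials out of a continuous recording.

    The window is relative to each event onset, in seconds; at the
    128 Hz default with a (0, 5) s window every trial has 640 samples.
    Events whose window overruns the recording are dropped with a logged
    warning rather than raising.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window end must exceed window start")
    n = int(round(rec.fs * (t1 - t0)))
    start_off = int(round(rec.fs * t0))
    trials, labels = [], []
    for onset, cls in rec.events:
        a = onset + start_off
        if a < 0 or a + n > rec.n_times:
            logger.warning(
                "dropping trial at sample %d (class %d): window [%d, %d) "
                "outside recording of length %d", onset, cls, a, a + n,
                rec.n_times,
            )
            continue
        trials.append(rec.samples[:, a : a + n])
        labels.append(cls)
    trials_arr = (
        np.stack(trials) if trials else np.empty((0, rec.n_channels, n))
    )
    return TrialSet(trials=trials_arr, labels=np.array(labels, int),
                    fs=rec.fs, window=(t0, t1))


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def save_trials(ts: TrialSet, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("trials", data=ts.trials)
        h5.create_dataset("labels", data=ts.labels)
        h5.create_dataset("fs", data=ts.fs)
        h5.attrs["window"] = ts.window


def load_trials(path: str | Path) -> TrialSet:
    with h5py.File(path, "r") as h5:
        return TrialSet(
            trials=h5["trials"][()],
            labels=h5["labels"][()],
            fs=float(h5["fs"][()]),
            window=tuple(h5.attrs["window"]),
        )


def save_features(path: str | Path, features: np.ndarray,
                  labels: np.ndarray) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("features", data=np.asarray(features, np.float32))
        h5.create_dataset("labels", data=np.asarray(labels, int))


def load_features(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as h5:
        return h5["features"][()], h5["labels"][()]
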