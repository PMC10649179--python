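"""Morlet joint time-frequency features and the CNN input tensor.

Each virtual-electrode series is decomposed with complex Morlet
wavelets on an integer frequency grid 8..30 Hz (23 bins), keeping all
640 time samples of the 5-s imagery window.  The two maps of a mirrored
electrode pair are stitched along the frequency axis (left 23 rows, then
right 23), and the nine pair blocks are stacked into the 640 x 46 x 9
tensor the classifier consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .virtual import ElectrodeSeries

logger = logging.getLogger(__name__)

DEFAULT_FREQS = np.arange(8.0, 31.0)     # 8..30 Hz inclusive, 23 bins


@dataclass
class TimeFrequencyMap:
    """Wavelet power, (n_freqs, n_times), power >= 0."""

    power: np.ndarray
    freqs: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, float)
        self.freqs = np.asarray(self.freqs, float)
        if self.power.shape[0] != len(self.freqs):
            raise ValueError("one power row per frequency required")


@dataclass
class FeatureTensor:
    """One trial's (640, 46, 9) time x frequency x pair stack."""

    data: np.ndarray
    label: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, np.float32)
        if self.data.ndim != 3:
            raise ValueError("tensor must be 3-D (time, freq-stack, pair)")


def morlet_power(series: ElectrodeSeries | np.ndarray,
                 freqs: np.ndarray = DEFAULT_FREQS,
                 n_cycles: np.ndarray | float | None = None,
                 fs: float | None = None) -> TimeFrequencyMap:
    """Squared magnitude of the complex Morlet transform of one series.

    ``n_cycles`` defaults to f/2 per frequency (fixed Q, a standard
    time-frequency trade-off for sensorimotor rhythms).  Same-length
    (zero-padded) convolution, so the map keeps every input sample;
    edge-affected columns are retained.
    """
    from mne.time_frequency import tfr_array_morlet

    if isinstance(series, ElectrodeSeries):
        values, fs_, label = series.values, series.fs, series.label
    else:
        values, fs_, label = np.asarray(series, float), fs, ""
        if fs_ is None:
            raise ValueError("fs is required for a bare array input")
    freqs = np.asarray(freqs, float)
    if n_cycles is None:
        n_cycles = freqs / 2.0
    # wavelet support must fit in the signal
    longest = int(np.max(np.atleast_1d(n_cycles) / freqs * fs_ * 5))
    if len(values) < longest:
        raise ValueError(
            f"series of {len(values)} samples shorter than the longest "
            f"wavelet ({longest} samples)")
    power = tfr_array_morlet(values[None, None, :], sfreq=fs_, freqs=freqs,
                             n_cycles=n_cycles, output="power",
                             verbose="error")[0, 0]
    return TimeFrequencyMap(power=power, freqs=freqs, fs=fs_, label=label)


def morlet_power_multi(series: np.ndarray, fs: float,
                       freqs: np.ndarray = DEFAULT_FREQS,
                       n_cycles: np.ndarray | float | None = None
                       ) -> np.ndarray:
    """Batched wavelet power: (n_trials, n_series, T) -> (n_trials,
    n_series, n_freqs, T)."""
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, float)
    if n_cycles is None:
        n_cycles = freqs / 2.0
    return tfr_array_morlet(np.asarray(series, float), sfreq=fs, freqs=freqs,
                            n_cycles=n_cycles, output="power",
                            verbose="error")


def stack_pair(left: TimeFrequencyMap, right: TimeFrequencyMap) -> np.ndarray:
    """Stitch a mirrored pair into one (n_times, 2*n_freqs) block.

    Columns 0..22 hold the left electrode's frequencies, 23..45 the
    right's; rows are time.
    """
    if left.power.shape != right.power.shape or \
            not np.array_equal(left.freqs, right.freqs):
        raise ValueError("left/right maps must share the frequency and "
                         "time axes")
    return np.concatenate([left.power.T, right.power.T], axis=1)


def build_tensor(pairs: list[np.ndarray], label: int) -> FeatureTensor:
    """Stack the 9 pair blocks (in order P1..P9) along the third axis."""
    if len(pairs) != 9:
        raise ValueError(f"expected 9 pair blocks, got {len(pairs)}")
    shapes = {p.shape for p in map(np.asarray, pairs)}
    if len(shapes) != 1:
        raise ValueError(f"pair blocks differ in shape: {shapes}")
    return FeatureTensor(data=np.stack(pairs, axis=2), label=int(label))


class TensorScaler(BaseEstimator, TransformerMixin):
    """Per-feature z-scoring with statistics from the training split only.

    Every (time, frequency, pair) cell is a feature.  Zero-variance
    features are centred but not scaled (logged).  The same fitted
    statistics are applied uniformly to every split.
    """

    def fit(self, X: np.ndarray, y=None) -> "TensorScaler":
        X = np.asarray(X)
        if X.ndim < 2 or len(X) == 0:
            raise ValueError("X must be a non-empty (n, ...) feature stack")
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        n_flat = int(np.sum(scale == 0))
        if n_flat:
            logger.info("%d zero-variance features centred only", n_flat)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = np.asarray(X)
        return ((X - self.mean_) / self.scale_).astype(np.float32)


def normalize_dataset(train: np.ndarray, *others: np.ndarray
                      ) -> tuple[np.ndarray, ...]:
    """Z-score all splits with statistics computed on ``train`` only."""
    scaler = TensorScaler().fit(train)
    return tuple(scaler.transform(x) for x in (train, *others))
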