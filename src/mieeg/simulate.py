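"""Synthetic motor-imagery EEG with known cortical ground truth.

Trials emulate the acquisition protocol: 8-s trials at 128 Hz with the
imagery cue at t = 0 and the imagery period spanning the first 5 s.
Each of the six classes activates a known cortical patch in the
hemisphere contralateral to the imagined limb (right-limb classes drive
left-hemisphere sources and vice versa) with a class-specific centre
frequency in the 8-30 Hz band; the mirror patch oscillates at reduced
amplitude, so contralateral power dominates as in real sensorimotor
lateralisation.  Source activity is projected to the 14 scalp channels
through the model lead field, then white sensor noise at a target SNR
and Poisson-timed frontal blink artifacts are added.

Every trial is reproducible from its integer seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .headmodel import LeadField
from .io import DEFAULT_CHANNELS, FRONTAL_CHANNELS, RawRecording, TrialSet
from .virtual import VirtualElectrode

#: per class: (task, hemisphere of the ACTIVE sources, centre freq Hz, pair)
CLASS_SIGNATURES: dict[int, tuple[str, str, float, str]] = {
    1: ("L-fist", "R", 10.0, "P3"),
    2: ("R-fist", "L", 10.0, "P3"),
    3: ("L-feet", "R", 16.0, "P1"),
    4: ("R-feet", "L", 16.0, "P1"),
    5: ("L-thumb", "R", 22.0, "P5"),
    6: ("R-thumb", "L", 22.0, "P5"),
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    ``snr_db = None`` disables sensor noise entirely (the "zero noise"
    condition); ``blink_rate`` is events per minute.  ``erd_depth`` is
    the fractional amplitude reduction of the ipsilateral mirror patch
    relative to the contralateral one, i.e. the depth of the lateralised
    power modulation.
    """

    fs: float = 128.0
    trial_seconds: float = 8.0
    imagery_window: tuple[float, float] = (0.0, 5.0)
    source_amplitude: float = 10e-9        # A*m, active patch
    background_amplitude: float = 1e-9     # A*m, every source
    erd_depth: float = 0.5
    snr_db: float | None = 10.0
    blink_rate: float = 10.0               # per minute
    blink_duration: float = 0.3            # seconds
    blink_gain: float = 10.0               # x background scalp RMS
    classes: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        t0, t1 = self.imagery_window
        if not (0 <= t0 < t1 <= self.trial_seconds):
            raise ValueError("imagery window must lie inside the trial")
        if self.blink_rate < 0 or self.blink_duration <= 0:
            raise ValueError("rates and durations must be positive")
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth is a fraction in [0, 1]")


@dataclass
class TrialTruth:
    """Ground truth of one simulated trial, for stage-level oracles."""

    class_id: int
    active_members: tuple[int, ...]
    mirror_members: tuple[int, ...]
    centre_freq: float
    amplitude: float
    blink_onsets: tuple[float, ...]
    clean_scalp: np.ndarray | None = None    # uV, source projection only
    noise: np.ndarray | None = None          # uV, sensor noise component


def _find_ve(ves: list[VirtualElectrode], hemisphere: str,
             pair: str) -> VirtualElectrode:
    for v in ves:
        if v.hemisphere == hemisphere and v.pair == pair:
            return v
    raise ValueError(f"no virtual electrode {hemisphere}/{pair}")


def _band_limited_noise(rng: np.random.Generator, shape: tuple[int, ...],
                        fs: float, band=(8.0, 30.0)) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)


def simulate_trial(
    config: SimulationConfig,
    class_id: int,
    seed: int,
    lead_field: LeadField,
    ves: list[VirtualElectrode],
    keep_components: bool = False,
) -> tuple[np.ndarray, TrialTruth]:
    """Simulate one trial; returns (channels x samples in uV, truth).

    Deterministic: the same seed yields a bit-identical trial.
    """
    if class_id not in CLASS_SIGNATURES:
        raise ValueError(f"invalid class id {class_id}; expected 1..6")
    rng = np.random.default_rng(seed)
    fs = config.fs
    n = int(round(config.trial_seconds * fs))
    t = np.arange(n) / fs
    K = lead_field.K                       # V / (A*m)
    M = K.shape[1]

    _, hemi, f0, pair = CLASS_SIGNATURES[class_id]
    active = _find_ve(ves, hemi, pair)
    mirror = _find_ve(ves, "L" if hemi == "R" else "R", pair)

    # imagery-window envelope with 0.25-s cosine ramps
    t0, t1 = config.imagery_window
    env = np.zeros(n)
    win = (t >= t0) & (t < t1)
    env[win] = 1.0
    ramp = int(0.25 * fs)
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    i0, i1 = int(t0 * fs), int(t1 * fs)
    env[i0 : i0 + ramp] *= up
    env[i1 - ramp : i1] *= up[::-1]

    J = config.background_amplitude * _band_limited_noise(rng, (M, n), fs)
    phase = rng.uniform(0, 2 * np.pi)
    # small per-trial jitter of frequency and amplitude
    f_trial = f0 + rng.normal(0, 0.2)
    amp = config.source_amplitude * (1 + 0.1 * rng.normal())
    osc = np.sin(2 * np.pi * f_trial * t + phase) * env
    J[list(active.members)] += amp * osc
    J[list(mirror.members)] += amp * (1 - config.erd_depth) * osc

    clean = (K @ J) * 1e6                  # uV
    x = clean.copy()

    # sensor noise at the requested SNR (power ratio over the trial)
    noise = np.zeros_like(x)
    if config.snr_db is not None:
        p_sig = np.mean(clean**2)
        p_noise = p_sig / 10 ** (config.snr_db / 10.0)
        noise = rng.normal(scale=np.sqrt(p_noise), size=x.shape)
        x = x + noise

    # frontal blink transients
    names = list(lead_field.electrode_names)
    blink_onsets: list[float] = []
    if config.blink_rate > 0:
        n_blinks = rng.poisson(config.blink_rate * config.trial_seconds / 60)
        dur = int(config.blink_duration * fs)
        shape_fn = 0.5 * (1 - np.cos(2 * np.pi * np.arange(dur) / dur))
        rms = np.sqrt(np.mean(x**2))
        weights = {"AF3": 1.0, "AF4": 1.0, "F7": 0.6, "F8": 0.6}
        for _ in range(n_blinks):
            onset = rng.uniform(0, config.trial_seconds - config.blink_duration)
            a = int(onset * fs)
            for ch, w in weights.items():
                if ch in names:
                    x[names.index(ch), a : a + dur] += \
                        config.blink_gain * rms * w * shape_fn
            blink_onsets.append(onset)

    truth = TrialTruth(
        class_id=class_id,
        active_members=active.members,
        mirror_members=mirror.members,
        centre_freq=f_trial,
        amplitude=amp,
        blink_onsets=tuple(blink_onsets),
        clean_scalp=clean if keep_components else None,
        noise=noise if keep_components else None,
    )
    return x, truth


def generate_dataset(
    config: SimulationConfig,
    n_per_class: int,
    seed: int,
    lead_field: LeadField,
    ves: list[VirtualElectrode],
) -> tuple[RawRecording, pd.DataFrame]:
    """Balanced labelled dataset as one continuous recording plus truth.

    Trials are concatenated back to back in shuffled class order with
    one event at each trial onset; the truth table holds one row per
    trial (class, active seed patch, amplitude, frequency, blinks).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    labels = np.repeat(list(config.classes), n_per_class)
    order_rng.shuffle(labels)
    trial_seeds = ss.generate_state(len(labels))

    n = int(round(config.trial_seconds * config.fs))
    n_ch = lead_field.K.shape[0]
    samples = np.empty((n_ch, n * len(labels)))
    events, rows = [], []
    for i, (cls, tseed) in enumerate(zip(labels, trial_seeds)):
        x, truth = simulate_trial(config, int(cls), int(tseed),
                                  lead_field, ves)
        samples[:, i * n : (i + 1) * n] = x
        events.append((i * n, int(cls)))
        rows.append({
            "trial": i, "onset_sample": i * n, "class": int(cls),
            "centre_freq": truth.centre_freq, "amplitude": truth.amplitude,
            "n_blinks": len(truth.blink_onsets),
            "active_members": list(truth.active_members),
            "seed": int(tseed),
        })
    rec = RawRecording(
        samples=samples,
        channel_names=list(lead_field.electrode_names)
        if lead_field.electrode_names else list(DEFAULT_CHANNELS),
        fs=config.fs,
        events=events,
    )
    return rec, pd.DataFrame(rows)


def dataset_to_trials(rec: RawRecording, config: SimulationConfig
                      ) -> TrialSet:
    """Epoch a generated recording into its imagery windows."""
    from .io import epoch_trials

    return epoch_trials(rec, config.imagery_window)
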