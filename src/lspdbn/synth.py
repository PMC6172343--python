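"""Synthetic signals: the two-tone test signal and surrogate motor-imagery EEG.

Two generators live here.  ``simulate_two_tone`` produces the noiseless
two-sinusoid test signal (4 Hz + 8 Hz, amplitude ratio 0.75 by default) used
to probe spectral estimators under data removal.  ``simulate_trial`` /
``generate_dataset`` emulate multi-channel motor-imagery EEG: a 1/f
background per channel plus mu (8-13 Hz) and beta (18-26 Hz) rhythm
oscillations whose power is attenuated (event-related desynchronization,
ERD) on a class-specific subset of channels.  The class label is therefore
encoded exactly where a sensorimotor-rhythm decoder expects it: in the
lateralized band power of the mu/beta rhythms.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

from ._utils import check_fraction, check_positive, derive_seed

__all__ = [
    "UniformSignal",
    "MotorImageryConfig",
    "Trial",
    "simulate_two_tone",
    "simulate_trial",
    "generate_dataset",
    "default_channel_map",
]


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled single-channel signal."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        check_positive("sampling_rate", self.sampling_rate)
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate


@dataclass(frozen=True)
class Trial:
    """One labelled multi-channel EEG epoch (channels x samples)."""

    data: np.ndarray
    sampling_rate: float
    label: int
    trial_id: int
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        check_positive("sampling_rate", self.sampling_rate)
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def default_channel_map(n_channels: int, class_count: int) -> Dict[int, Tuple[int, ...]]:
    """Assign each class a disjoint, contiguous block of affected channels.

    One block is left unaffected by any class so that every trial contains
    reference channels with full rhythm power.
    """
    group = max(1, n_channels // (class_count + 1))
    mapping = {}
    for k in range(class_count):
        lo = k * group
        hi = min(n_channels, lo + group)
        if lo >= n_channels:
            raise ValueError("not enough channels for the requested class count")
        mapping[k] = tuple(range(lo, hi))
    return mapping


@dataclass(frozen=True)
class MotorImageryConfig:
    """Generator settings for surrogate motor-imagery EEG.

    The defaults are a desk-scale stand-in for a 64-channel, 1 kHz recording:
    16 channels at 250 Hz, 4-s trials, three imagery classes.  ``erd_depth``
    is the fractional attenuation of rhythm amplitude on the channels a class
    affects; 0 removes the class signal entirely, 1 silences the rhythm on
    affected channels.  Use :meth:`paper_scale` for the full-scale preset.
    """

    n_channels: int = 16
    sampling_rate: float = 250.0
    trial_duration: float = 4.0
    class_count: int = 3
    erd_depth: float = 0.6
    rhythm_bands: Tuple[Tuple[float, float], ...] = ((8.0, 13.0), (18.0, 26.0))
    rhythm_amplitudes: Tuple[float, ...] = (1.0, 0.7)
    oscillators_per_band: int = 2
    amplitude_jitter: float = 0.2
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    white_noise_fraction: float = 0.3
    affected_channel_map: Dict[int, Tuple[int, ...]] = field(default=None)  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        check_positive("n_channels", self.n_channels)
        check_positive("sampling_rate", self.sampling_rate)
        check_positive("trial_duration", self.trial_duration)
        check_fraction("erd_depth", self.erd_depth)
        if self.class_count < 2:
            raise ValueError("class_count must be >= 2")
        if len(self.rhythm_amplitudes) != len(self.rhythm_bands):
            raise ValueError("one amplitude per rhythm band required")
        if self.affected_channel_map is None:
            object.__setattr__(
                self, "affected_channel_map",
                default_channel_map(self.n_channels, self.class_count))
        for label, channels in self.affected_channel_map.items():
            if not 0 <= label < self.class_count:
                raise ValueError(f"channel map has unknown class {label}")
            if any(not 0 <= c < self.n_channels for c in channels):
                raise ValueError(f"channel map for class {label} exceeds channel range")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.trial_duration))

    @classmethod
    def paper_scale(cls, **overrides) -> "MotorImageryConfig":
        """Full-scale preset: 64 channels at 1 kHz (the study's geometry)."""
        params = dict(n_channels=64, sampling_rate=1000.0)
        params.update(overrides)
        return cls(**params)


def simulate_two_tone(sampling_rate: float = 100.0, duration: float = 10.0,
                      amp_ratio: float = 0.75, f_low: float = 4.0,
                      f_high: float = 8.0) -> UniformSignal:
    """Mix two sinusoids: ``amp_ratio*sin(2*pi*f_low*t) + sin(2*pi*f_high*t)``.

    The high-frequency component has unit amplitude; ``amp_ratio`` is the
    amplitude of the low tone relative to it.  The default tones at 4 and
    8 Hz with ratio 0.75 are the standard probe signal for comparing
    spectral estimators on gappy data.
    """
    check_positive("sampling_rate", sampling_rate)
    check_positive("duration", duration)
    check_positive("f_low", f_low)
    check_positive("f_high", f_high)
    if amp_ratio < 0:
        raise ValueError("amp_ratio must be non-negative")
    if f_high >= sampling_rate / 2:
        raise ValueError("f_high must lie below the Nyquist frequency")
    n = int(round(sampling_rate * duration))
    t = np.arange(n) / sampling_rate
    values = amp_ratio * np.sin(2 * np.pi * f_low * t) + np.sin(2 * np.pi * f_high * t)
    return UniformSignal(values=values, sampling_rate=sampling_rate)


def _colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^exponent noise of length n, unit standard deviation."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC component
    colored = np.fft.irfft(spectrum * scale, n)
    sd = colored.std()
    return colored / sd if sd > 0 else colored


def simulate_trial(config: MotorImageryConfig, label: int, seed: int) -> Trial:
    """Generate one trial of surrogate motor-imagery EEG.

    Every channel carries 1/f background noise plus rhythm oscillations in
    each configured band (a few random-frequency, random-phase sinusoids per
    band, with mild trial-to-trial amplitude jitter).  Channels listed in
    ``affected_channel_map[label]`` have their rhythm amplitude multiplied by
    ``1 - erd_depth`` -- the ERD signature that identifies the class.
    """
    if not 0 <= label < config.class_count:
        raise ValueError(f"unknown label {label} for {config.class_count} classes")
    rng = np.random.default_rng(seed)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    affected = set(config.affected_channel_map.get(label, ()))

    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        noise = _colored_noise(n, config.noise_exponent, rng)
        white = rng.standard_normal(n)
        frac = config.white_noise_fraction
        background = config.noise_scale * ((1 - frac) * noise + frac * white)

        rhythm = np.zeros(n)
        atten = (1.0 - config.erd_depth) if ch in affected else 1.0
        for (low, high), amp in zip(config.rhythm_bands, config.rhythm_amplitudes):
            for _ in range(config.oscillators_per_band):
                f = rng.uniform(low, high)
                phase = rng.uniform(0, 2 * np.pi)
                jitter = np.exp(config.amplitude_jitter * rng.standard_normal())
                rhythm += atten * amp * jitter * np.sin(2 * np.pi * f * t + phase)
        data[ch] = background + rhythm

    return Trial(data=data, sampling_rate=config.sampling_rate, label=label,
                 trial_id=seed, subject_id="synthetic")


def generate_dataset(config: MotorImageryConfig, trials_per_class: int,
                     seed: int) -> list[Trial]:
    """Generate a balanced, class-shuffled dataset of trials.

    Exactly ``trials_per_class`` trials per class; presentation order is
    randomized by ``seed`` (mimicking randomized cue sequences); trial ids
    are unique and the whole dataset is a pure function of (config, seed).
    """
    if trials_per_class < 1:
        raise ValueError("trials_per_class must be >= 1")
    labels = np.repeat(np.arange(config.class_count), trials_per_class)
    order_rng = np.random.default_rng(derive_seed(seed, 0xC1A55))
    labels = labels[order_rng.permutation(len(labels))]
    trials = []
    for i, label in enumerate(labels):
        trial_seed = derive_seed(seed, i)
        trial = simulate_trial(config, int(label), trial_seed)
        trials.append(replace(trial, trial_id=i))
    return trials
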