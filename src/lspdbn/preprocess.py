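"""Filtering, sliding-window segmentation, and point/chunk data removal.

The removal operations are the heart of the "incomplete EEG" construction:
instead of rejecting a contaminated segment outright, individual samples
(point removal: the data-loss model) or contiguous blocks of samples
(chunk removal: the extreme-artifact model) are deleted.  Crucially, the
retained samples keep their ORIGINAL timestamps, which turns the segment
into a non-uniformly sampled series -- the premise of the least-squares
spectral estimator downstream.  Deletion uses the same index set on every
channel of a segment, modelling frame-wise loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Literal

import numpy as np
from scipy import signal as sps

from ._utils import check_positive
from .synth import Trial

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "RemovalSpec",
    "IncompleteSegment",
    "bandpass_filter",
    "notch_filter",
    "segment_trial",
    "remove_points",
    "remove_chunks",
    "apply_removal",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    Defaults follow the standard motor-imagery setting: fifth order,
    pass band 8-35 Hz, output scaled by 1.5.  The filter is applied
    forward-backward (zero phase), so the effective magnitude response is
    ``|H(f)|**2`` times the gain.
    """

    order: int = 5
    low_cut: float = 8.0
    high_cut: float = 35.0
    gain: float = 1.5

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        check_positive("gain", self.gain)

    def sos(self, sampling_rate: float) -> np.ndarray:
        if self.high_cut >= sampling_rate / 2:
            raise ValueError("high_cut must lie below the Nyquist frequency")
        return sps.butter(self.order, [self.low_cut, self.high_cut],
                          btype="bandpass", fs=sampling_rate, output="sos")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window segmentation: 1-s windows every 0.2 s by default."""

    window_length: float = 1.0
    step: float = 0.2

    def __post_init__(self) -> None:
        check_positive("window_length", self.window_length)
        if not 0 < self.step <= self.window_length:
            raise ValueError("need 0 < step <= window_length")


@dataclass(frozen=True)
class RemovalSpec:
    """How much data to delete and in what form.

    ``proportion`` is the target fraction of samples to delete.  For chunk
    removal the segment is first partitioned into blocks whose widths are
    drawn from Normal(chunk_width_mean, chunk_width_sd) rounded to integers
    (minimum 1); randomly chosen blocks are deleted until the deleted count
    first reaches the target, so the realized fraction can overshoot by at
    most one chunk.
    """

    form: Literal["point", "chunk"] = "point"
    proportion: float = 0.1
    chunk_width_mean: float = 10.0
    chunk_width_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.form not in ("point", "chunk"):
            raise ValueError(f"unknown removal form {self.form!r}")
        if not 0 <= self.proportion < 1:
            raise ValueError("proportion must lie in [0, 1)")
        check_positive("chunk_width_mean", self.chunk_width_mean)
        if self.chunk_width_sd < 0:
            raise ValueError("chunk_width_sd must be >= 0")


@dataclass(frozen=True)
class IncompleteSegment:
    """A windowed segment after (possible) sample deletion.

    ``values`` holds the retained amplitudes (channels x retained samples);
    ``timestamps`` the retained sample times in seconds relative to segment
    start, shared across channels and strictly increasing.  A freshly cut
    segment has ``retained_fraction == 1``.
    """

    values: np.ndarray
    timestamps: np.ndarray
    sampling_rate: float
    original_length: int
    label: int
    source_trial: int
    segment_index: int

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        timestamps = np.asarray(self.timestamps, dtype=float)
        if values.shape[1] != len(timestamps):
            raise ValueError("values and timestamps disagree on sample count")
        if len(timestamps) > 1 and not np.all(np.diff(timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "timestamps", timestamps)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_retained(self) -> int:
        return self.values.shape[1]

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.original_length


def bandpass_filter(trial: Trial, spec: FilterSpec = FilterSpec()) -> Trial:
    """Zero-phase Butterworth band-pass, channel by channel, times the gain."""
    sos = spec.sos(trial.sampling_rate)
    filtered = sps.sosfiltfilt(sos, trial.data, axis=1) * spec.gain
    return Trial(data=filtered, sampling_rate=trial.sampling_rate,
                 label=trial.label, trial_id=trial.trial_id,
                 subject_id=trial.subject_id)


def notch_filter(trial: Trial, freq: float = 50.0, quality: float = 30.0) -> Trial:
    """Zero-phase IIR notch at ``freq`` (power-line rejection)."""
    if freq >= trial.sampling_rate / 2:
        raise ValueError("notch frequency must lie below the Nyquist frequency")
    b, a = sps.iirnotch(freq, quality, fs=trial.sampling_rate)
    filtered = sps.filtfilt(b, a, trial.data, axis=1)
    return Trial(data=filtered, sampling_rate=trial.sampling_rate,
                 label=trial.label, trial_id=trial.trial_id,
                 subject_id=trial.subject_id)


def segment_trial(trial: Trial, spec: WindowSpec = WindowSpec()) -> List[IncompleteSegment]:
    """Cut a trial into overlapping complete segments.

    Window k covers ``[k*step, k*step + window_length)``; the number of
    segments is ``floor((duration - window_length)/step) + 1`` (a 4-s trial
    with 1-s windows every 0.2 s yields 16).  Segment timestamps restart at
    zero: ``t_i = i / sampling_rate``.
    """
    win = int(round(spec.window_length * trial.sampling_rate))
    step = int(round(spec.step * trial.sampling_rate))
    if win > trial.n_samples:
        raise ValueError("trial is shorter than the analysis window")
    n_segments = (trial.n_samples - win) // step + 1
    timestamps = np.arange(win) / trial.sampling_rate
    segments = []
    for k in range(n_segments):
        start = k * step
        segments.append(IncompleteSegment(
            values=trial.data[:, start:start + win],
            timestamps=timestamps,
            sampling_rate=trial.sampling_rate,
            original_length=win,
            label=trial.label,
            source_trial=trial.trial_id,
            segment_index=k,
        ))
    return segments


def _point_keep_mask(n: int, proportion: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean keep-mask deleting exactly round(proportion*n) indices."""
    n_remove = int(round(proportion * n))
    mask = np.ones(n, dtype=bool)
    if n_remove > 0:
        removed = rng.choice(n, size=n_remove, replace=False)
        mask[removed] = False
    return mask


def _chunk_keep_mask(n: int, proportion: float, width_mean: float,
                     width_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Keep-mask from sequential chunk partition + random chunk deletion."""
    mask = np.ones(n, dtype=bool)
    if proportion <= 0:
        return mask
    # Partition [0, n) into chunks with Normal-distributed widths (rounded,
    # clipped to >= 1, last chunk truncated to fit).
    widths = np.empty(0, dtype=int)
    while widths.sum() < n:
        draw = np.maximum(1, np.rint(rng.normal(
            width_mean, width_sd,
            size=int(n / max(width_mean, 1) + 6 * width_sd + 8))).astype(int))
        widths = np.concatenate([widths, draw])
    ends = np.minimum(np.cumsum(widths), n)
    last = int(np.searchsorted(ends, n)) + 1
    ends = ends[:last]
    starts = np.concatenate([[0], ends[:-1]])
    # Delete randomly ordered chunks until the deleted count first reaches
    # the target.
    order = rng.permutation(len(starts))
    sizes = (ends - starts)[order]
    cum = np.cumsum(sizes)
    k = int(np.searchsorted(cum, proportion * n)) + 1
    for idx in order[:k]:
        mask[starts[idx]:ends[idx]] = False
    return mask


def _apply_mask(segment: IncompleteSegment, mask: np.ndarray) -> IncompleteSegment:
    return IncompleteSegment(
        values=segment.values[:, mask],
        timestamps=segment.timestamps[mask],
        sampling_rate=segment.sampling_rate,
        original_length=segment.original_length,
        label=segment.label,
        source_trial=segment.source_trial,
        segment_index=segment.segment_index,
    )


def remove_points(segment: IncompleteSegment, spec: RemovalSpec) -> IncompleteSegment:
    """Delete exactly ``round(proportion * N)`` random samples (all channels).

    Retained samples keep their original timestamps, producing a
    non-uniformly sampled segment.
    """
    if segment.retained_fraction < 1:
        warnings.warn("applying removal to an already-incomplete segment")
    rng = np.random.default_rng(spec.seed)
    mask = _point_keep_mask(segment.n_retained, spec.proportion, rng)
    return _apply_mask(segment, mask)


def remove_chunks(segment: IncompleteSegment, spec: RemovalSpec) -> IncompleteSegment:
    """Delete randomly chosen contiguous chunks until >= proportion*N samples are gone.

    Chunk widths are drawn from Normal(chunk_width_mean, chunk_width_sd),
    rounded and clipped to >= 1, with the final chunk truncated to fit the
    segment.  The same chunks are deleted on every channel.
    """
    if segment.retained_fraction < 1:
        warnings.warn("applying removal to an already-incomplete segment")
    rng = np.random.default_rng(spec.seed)
    mask = _chunk_keep_mask(segment.n_retained, spec.proportion,
                            spec.chunk_width_mean, spec.chunk_width_sd, rng)
    return _apply_mask(segment, mask)


def apply_removal(segment: IncompleteSegment, spec: RemovalSpec) -> IncompleteSegment:
    """Dispatch to point or chunk removal according to ``spec.form``."""
    if spec.form == "point":
        return remove_points(segment, spec)
    return remove_chunks(segment, spec)
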