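"""Spectral power estimation and band-power feature construction.

The central estimator is the least-squares Lomb-Scargle periodogram (LSP):
at each trial frequency ``omega`` the series ``x(t_i)`` is fit with
``a*cos(omega t_i) + b*sin(omega t_i)`` by solving the 2x2 normal equations

    R = sum_i [cos, sin]^T [cos, sin],    r = sum_i [cos, sin]^T x(t_i),
    [a, b]^T = R^{-1} r,                  P(omega) = (1/N) r^T R^{-1} r.

Because the fit uses the actual (possibly non-uniform) timestamps, the
estimate degrades gracefully when samples are deleted -- unlike the FFT and
Welch baselines, which here receive the retained samples concatenated and
re-interpreted as uniform at the original rate (the simplest treatment a
uniform-grid method admits for gappy data).

For a sinusoid of amplitude A, P at its frequency converges to A**2/2 on
dense sampling, so sub-band averages of P are amplitude-scale band powers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .preprocess import IncompleteSegment

__all__ = [
    "SpectrumEstimate",
    "SubbandSpec",
    "NormalizationStats",
    "default_freq_grid",
    "lsp_power_at",
    "lsp_spectrum",
    "fft_periodogram",
    "welch_periodogram",
    "normalize_power_by_retention",
    "subband_features",
    "fit_minmax",
    "apply_minmax",
]

#: Ridge added to the diagonal of R (scaled by N) when it is near-singular.
_RIDGE = 1e-10


@dataclass(frozen=True)
class SpectrumEstimate:
    """Per-channel power on a frequency grid, tagged with its estimator."""

    freqs: np.ndarray
    power: np.ndarray  # channels x freqs
    estimator: str
    retained_fraction: float
    normalized_by_retention: bool = False

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if power.shape[1] != len(freqs):
            raise ValueError("power and freqs disagree on grid size")
        if len(freqs) > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


@dataclass(frozen=True)
class SubbandSpec:
    """Ordered, non-overlapping sub-bands; half-open intervals [low, high).

    The default partitions 8-28 Hz into alpha, sigma, low-beta and
    high-beta, the bands whose power modulation discriminates motor-imagery
    classes.
    """

    bands: Tuple[Tuple[float, float], ...] = (
        (8.0, 13.0), (13.0, 18.0), (18.0, 23.0), (23.0, 28.0))
    labels: Tuple[str, ...] = ("alpha", "sigma", "low_beta", "high_beta")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.bands):
            raise ValueError("one label per band required")
        flat = [edge for band in self.bands for edge in band]
        if any(b[0] >= b[1] for b in self.bands) or flat != sorted(flat):
            raise ValueError("bands must be ascending and non-overlapping")

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class NormalizationStats:
    """Per-dimension min/max learned on training features (Eq.-style min-max)."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        if mins.shape != maxs.shape or np.any(maxs < mins):
            raise ValueError("invalid min/max statistics")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)


def default_freq_grid(low: float = 1.0, high: float = 35.0,
                      step: float = 0.5) -> np.ndarray:
    """Analysis grid: 0.5 Hz spacing over [1, 35] Hz by default."""
    return np.arange(low, high + step / 2, step)


def _lsp_components(timestamps: np.ndarray, omegas: np.ndarray):
    """Trig sums and cross-products shared by all channels of a segment."""
    phase = np.outer(omegas, timestamps)  # F x N
    c = np.cos(phase)
    s = np.sin(phase)
    scc = np.einsum("fn,fn->f", c, c)
    sss = np.einsum("fn,fn->f", s, s)
    scs = np.einsum("fn,fn->f", c, s)
    return c, s, scc, sss, scs


def _quadratic_power(rc, rs, scc, sss, scs, n):
    """P = (1/N) r^T R^{-1} r via the closed-form 2x2 inverse, with ridge."""
    det = scc * sss - scs**2
    # Near-singular normal matrix: regularize, then give up to zero power.
    bad = det <= _RIDGE * n
    if np.any(bad):
        scc = scc + _RIDGE * n
        sss = sss + _RIDGE * n
        det = scc * sss - scs**2
    power = (sss * rc**2 - 2 * scs * rc * rs + scc * rs**2) / det / n
    still_bad = det <= 0
    if np.any(still_bad):
        warnings.warn("degenerate frequency in LSP; returning zero power")
        power = np.where(still_bad, 0.0, power)
    return np.maximum(power, 0.0)


def lsp_power_at(timestamps: np.ndarray, values: np.ndarray, omega: float) -> float:
    """Least-squares spectral power of one channel at angular frequency omega."""
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.ndim != 1 or x.shape != t.shape:
        raise ValueError("timestamps and values must be matching 1-D arrays")
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    c, s, scc, sss, scs = _lsp_components(t, np.asarray([omega], dtype=float))
    rc = c @ x
    rs = s @ x
    return float(_quadratic_power(rc, rs, scc, sss, scs, len(t))[0])


def lsp_spectrum(segment: IncompleteSegment,
                 freqs: Optional[np.ndarray] = None) -> SpectrumEstimate:
    """LSP power for every channel of a segment on a frequency grid (Hz)."""
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency grid is empty")
    nyquist = segment.sampling_rate / 2
    if np.any(freqs <= 0) or np.any(freqs >= nyquist):
        raise ValueError("grid must lie inside (0, Nyquist of the original rate)")
    omegas = 2 * np.pi * freqs
    t = segment.timestamps
    n = segment.n_retained
    c, s, scc, sss, scs = _lsp_components(t, omegas)
    rc = c @ segment.values.T  # F x C
    rs = s @ segment.values.T
    power = _quadratic_power(rc.T, rs.T, scc[None, :], sss[None, :],
                             scs[None, :], n)
    return SpectrumEstimate(freqs=freqs, power=power, estimator="lsp",
                            retained_fraction=segment.retained_fraction)


def lsp_spectra_batch(values: np.ndarray, masks: np.ndarray,
                      sampling_rate: float, freqs: np.ndarray,
                      block: int = 512) -> np.ndarray:
    """Vectorized LSP over many equally-gridded segments.

    ``values`` is (segments x channels x samples) on the ORIGINAL uniform
    grid; ``masks`` (segments x samples) marks retained samples.  Because
    retained timestamps are subsets of one uniform grid, the trig tables are
    computed once and masked per segment, which makes whole-dataset feature
    extraction a handful of matrix products.  Returns power of shape
    (segments x channels x freqs).  Exactly equivalent to calling
    :func:`lsp_spectrum` per segment.
    """
    n_seg, n_ch, n = values.shape
    t = np.arange(n) / sampling_rate
    omegas = 2 * np.pi * np.asarray(freqs, dtype=float)
    phase = np.outer(omegas, t)
    c = np.cos(phase)  # F x N
    s = np.sin(phase)
    cc, ss, cs = c * c, s * s, c * s
    out = np.empty((n_seg, n_ch, len(omegas)))
    for lo in range(0, n_seg, block):
        hi = min(lo + block, n_seg)
        m = masks[lo:hi].astype(float)  # B x N
        scc = m @ cc.T  # B x F
        sss = m @ ss.T
        scs = m @ cs.T
        vm = values[lo:hi] * m[:, None, :]  # B x C x N
        rc = vm @ c.T  # B x C x F
        rs = vm @ s.T
        counts = m.sum(axis=1)[:, None, None]
        out[lo:hi] = _quadratic_power(rc, rs, scc[:, None, :], sss[:, None, :],
                                      scs[:, None, :], counts)
    return out


def _concatenated_uniform(segment: IncompleteSegment) -> np.ndarray:
    """Retained samples re-interpreted as uniform at the original rate."""
    return segment.values


def fft_periodogram(segment: IncompleteSegment,
                    nfft: Optional[int] = None) -> SpectrumEstimate:
    """Plain periodogram of the concatenated retained samples.

    The FFT is zero-padded to ``nfft`` (default: the segment's original
    length) so the frequency grid keeps its resolution even when most
    samples are gone.
    """
    x = _concatenated_uniform(segment)
    if x.shape[1] < 8:
        raise ValueError("need at least 8 retained samples")
    if nfft is None:
        nfft = max(segment.original_length, x.shape[1])
    freqs, power = sps.periodogram(x, fs=segment.sampling_rate,
                                   detrend=False, nfft=nfft, axis=1)
    keep = freqs > 0
    return SpectrumEstimate(freqs=freqs[keep], power=power[:, keep],
                            estimator="fft",
                            retained_fraction=segment.retained_fraction)


def welch_periodogram(segment: IncompleteSegment,
                      window_length: Optional[int] = None,
                      overlap: float = 0.5,
                      nfft: Optional[int] = None) -> SpectrumEstimate:
    """Welch-averaged periodogram of the concatenated retained samples.

    ``window_length`` is in samples (default: a quarter of the retained
    length, at least 32, capped at the retained length); with fewer samples
    than one window it degrades to a single window with a warning.  Windows
    are zero-padded to ``nfft`` (default: the segment's original length) so
    the grid resolution is independent of how much data survived.
    """
    x = _concatenated_uniform(segment)
    n = x.shape[1]
    if n < 8:
        raise ValueError("need at least 8 retained samples")
    if window_length is None:
        window_length = min(n, max(32, n // 4))
    if window_length > n:
        warnings.warn("fewer samples than one Welch window; using a single window")
        window_length = n
    if nfft is None:
        nfft = max(segment.original_length, window_length)
    noverlap = int(window_length * overlap)
    freqs, power = sps.welch(x, fs=segment.sampling_rate, nperseg=window_length,
                             noverlap=noverlap, detrend=False, nfft=nfft, axis=1)
    keep = freqs > 0
    return SpectrumEstimate(freqs=freqs[keep], power=power[:, keep],
                            estimator="welch",
                            retained_fraction=segment.retained_fraction)


def normalize_power_by_retention(spectrum: SpectrumEstimate) -> SpectrumEstimate:
    """Divide the power by the retained fraction, putting estimates on one scale."""
    if spectrum.normalized_by_retention:
        raise ValueError("spectrum is already retention-normalized")
    if spectrum.retained_fraction <= 0:
        raise ValueError("retained_fraction must be positive")
    return replace(spectrum, power=spectrum.power / spectrum.retained_fraction,
                   normalized_by_retention=True)


def subband_features(spectrum: SpectrumEstimate,
                     bands: SubbandSpec = SubbandSpec()) -> np.ndarray:
    """Mean power per (channel, band), concatenated channel-major.

    The result is the flat feature vector
    ``[p_11, ..., p_1B, p_21, ..., p_CB]`` of length ``B * C`` (256 for 64
    channels and the default four bands).
    """
    features = []
    masks = []
    for low, high in bands.bands:
        mask = (spectrum.freqs >= low) & (spectrum.freqs < high)
        if not np.any(mask):
            raise ValueError(f"band [{low}, {high}) contains no grid points")
        masks.append(mask)
    per_band = np.stack([spectrum.power[:, m].mean(axis=1) for m in masks],
                        axis=1)  # C x B
    return per_band.reshape(-1)


def subband_features_batch(power: np.ndarray, freqs: np.ndarray,
                           bands: SubbandSpec = SubbandSpec()) -> np.ndarray:
    """Vectorized :func:`subband_features` for (segments x channels x freqs)."""
    cols = []
    for low, high in bands.bands:
        mask = (freqs >= low) & (freqs < high)
        if not np.any(mask):
            raise ValueError(f"band [{low}, {high}) contains no grid points")
        cols.append(power[..., mask].mean(axis=-1))  # S x C
    per_band = np.stack(cols, axis=-1)  # S x C x B
    return per_band.reshape(power.shape[0], -1)


def peak_background_ratio(spectrum: SpectrumEstimate,
                          peak_freqs: Sequence[float],
                          exclude_bins: int = 3) -> Tuple[float, bool]:
    """Mean power at the grid points nearest ``peak_freqs`` over the median
    off-peak power, plus a detectability flag.

    The background excludes ``exclude_bins`` grid points on either side of
    each peak.  A peak set counts as *detected* when every peak is a local
    maximum on the grid and exceeds the median background.
    """
    p = spectrum.power.mean(axis=0)
    freqs = spectrum.freqs
    idx = [int(np.argmin(np.abs(freqs - f))) for f in peak_freqs]
    background = np.ones(len(freqs), dtype=bool)
    for i in idx:
        background[max(0, i - exclude_bins):i + exclude_bins + 1] = False
    if not np.any(background):
        raise ValueError("no background bins left on this grid")
    med = float(np.median(p[background]))
    detected = all(
        0 < i < len(freqs) - 1 and p[i] >= p[i - 1] and p[i] >= p[i + 1]
        and p[i] > med for i in idx)
    ratio = float(np.mean(p[idx]) / med) if med > 0 else np.inf
    return ratio, detected


def fit_minmax(features: np.ndarray) -> NormalizationStats:
    """Learn per-dimension min/max from a (samples x dims) training matrix."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors to fit min-max")
    return NormalizationStats(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_minmax(features: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Scale features to [0, 1] with training-set statistics.

    Test values outside the training range map outside [0, 1] (no clipping);
    dimensions that were constant in training map to 0.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    span = stats.maxs - stats.mins
    out = np.zeros_like(X)
    ok = span > 0
    out[:, ok] = (X[:, ok] - stats.mins[ok]) / span[ok]
    return out
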