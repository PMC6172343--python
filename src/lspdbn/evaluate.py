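"""Experiment harness: splits, cross-validation folds, removal-robustness curves.

`run_removal_curve` is the package's headline experiment: starting from a
set of labelled trials it band-pass filters, segments, deletes data (point
or chunk form, one ratio at a time), extracts band-power features with a
chosen spectral estimator, min-max normalizes on the training split only,
trains a classifier, and records test accuracy -- for every combination of
(estimator, classifier, removal form, removal ratio, seed).  The resulting
tidy table is what the robustness claims are read from: the accuracy
*spread* across removal ratios measures how gracefully a feature extractor
degrades as data goes missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as spstats

from ._utils import derive_seed
from .baselines import SvmConfig, predict_svm, train_svm_committee
from .dbn import TrainConfig, fit_dbn, predict
from .preprocess import (FilterSpec, RemovalSpec, WindowSpec, _chunk_keep_mask,
                         _point_keep_mask, bandpass_filter, segment_trial)
from .spectral import (SubbandSpec, default_freq_grid, fft_periodogram,
                       lsp_spectra_batch, normalize_power_by_retention,
                       subband_features, subband_features_batch,
                       welch_periodogram, apply_minmax, fit_minmax)
from .synth import Trial

__all__ = [
    "SplitSpec",
    "Split",
    "RemovalCurve",
    "HARNESS_DBN_CONFIG",
    "split_dataset",
    "kfold_indices",
    "paired_ttest",
    "majority_vote_trial",
    "accuracy_spread",
    "run_removal_curve",
    "two_tone_robustness",
]

#: Desk-scale DBN training schedule used by the evaluation harness.  The CD
#: learning rates, weight decay and sparsity target keep their standard
#: values; epochs and batch size are sized for repeated fits on the
#: canonical dataset (about 3600 training segments, where 10+25 epochs give
#: plenty of SGD steps).  For substantially smaller feature sets prefer the
#: default :class:`~lspdbn.dbn.TrainConfig` schedule (50 pre-training and
#: 200 fine-tuning epochs), which converges regardless of dataset size.
HARNESS_DBN_CONFIG = TrainConfig(pretrain_epochs=10, finetune_epochs=25,
                                 batch_size=100, finetune_lr=0.5,
                                 lr_decay=0.93)

DEFAULT_RATIOS = tuple(np.round(np.arange(0.1, 0.81, 0.1), 2))


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: 75/25 by default, at segment or trial granularity."""

    train_fraction: float = 0.75
    mode: str = "segment"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.mode not in ("segment", "trial"):
            raise ValueError("mode must be 'segment' or 'trial'")


@dataclass(frozen=True)
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray


def split_dataset(n_samples: int, trial_ids: np.ndarray,
                  spec: SplitSpec) -> Split:
    """Random train/test partition of segment indices.

    Segment mode samples segments independently (train size =
    round(fraction * n)); trial mode keeps all segments of a trial on the
    same side, so segments of one trial never leak across the split.
    """
    if n_samples == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "segment":
        n_train = int(round(spec.train_fraction * n_samples))
        if n_train == 0 or n_train == n_samples:
            raise ValueError("train_fraction yields an empty side")
        order = rng.permutation(n_samples)
        return Split(np.sort(order[:n_train]), np.sort(order[n_train:]))
    trial_ids = np.asarray(trial_ids)
    unique = np.unique(trial_ids)
    n_train_trials = int(round(spec.train_fraction * len(unique)))
    if n_train_trials == 0 or n_train_trials == len(unique):
        raise ValueError("train_fraction yields an empty side")
    chosen = set(unique[rng.permutation(len(unique))[:n_train_trials]])
    mask = np.asarray([t in chosen for t in trial_ids])
    return Split(np.flatnonzero(mask), np.flatnonzero(~mask))


def kfold_indices(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold id per index: an exact partition with fold sizes differing by <= 1."""
    if n < k:
        raise ValueError("need at least k samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    order = rng.permutation(n)
    start = 0
    for fold, size in enumerate(sizes):
        folds[order[start:start + size]] = fold
        start += size
    return folds


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def paired_ttest(acc_a: Sequence[float], acc_b: Sequence[float]) -> TTestResult:
    """Classical paired Student's t-test on per-replicate differences."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        return TTestResult(statistic=np.nan, pvalue=np.nan, degenerate=True)
    res = spstats.ttest_rel(a, b)
    return TTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def majority_vote_trial(segment_labels: np.ndarray,
                        trial_ids: np.ndarray,
                        n_classes: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Modal predicted class per trial; ties go to the lowest class index.

    Returns (unique trial ids, voted label per trial).
    """
    labels = np.asarray(segment_labels, dtype=int)
    trial_ids = np.asarray(trial_ids)
    if len(labels) != len(trial_ids) or len(labels) == 0:
        raise ValueError("need one predicted label per segment")
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    unique = np.unique(trial_ids)
    voted = np.empty(len(unique), dtype=int)
    for i, t in enumerate(unique):
        counts = np.bincount(labels[trial_ids == t], minlength=n_classes)
        voted[i] = int(np.argmax(counts))
    return unique, voted


@dataclass
class RemovalCurve:
    """Tidy accuracy table: one row per (estimator, classifier, form, ratio, seed)."""

    results: pd.DataFrame
    ratios: Tuple[float, ...]

    def summary(self) -> pd.DataFrame:
        """Mean +/- sd accuracy per curve cell."""
        return (self.results
                .groupby(["estimator", "classifier", "form", "ratio"])
                ["accuracy"].agg(["mean", "std", "count"]).reset_index())


def accuracy_spread(curve: RemovalCurve,
                    ratios: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Max-minus-min accuracy across the removal-ratio range, per seed.

    The spread is the robustness statistic: a flat curve (small spread)
    means the feature/classifier pair tolerates data removal.  Rows with
    ratio 0 (intact) are excluded by default.
    """
    if ratios is None:
        ratios = [r for r in curve.ratios if r > 0]
    df = curve.results[curve.results["ratio"].isin(ratios)]
    have = df.groupby(["estimator", "classifier", "form", "seed"])["ratio"].nunique()
    if (have < len(set(ratios))).any():
        raise ValueError("curve does not cover all requested ratios")
    spread = (df.groupby(["estimator", "classifier", "form", "seed"])
              ["accuracy"].agg(lambda a: a.max() - a.min()))
    return spread.rename("spread").reset_index()


def two_tone_robustness(ratios: Sequence[float] = DEFAULT_RATIOS,
                        n_seeds: int = 100,
                        base_seed: int = 0,
                        estimators: Sequence[str] = ("lsp", "fft", "welch"),
                        sampling_rate: float = 100.0,
                        duration: float = 10.0,
                        amp_ratio: float = 0.75,
                        f_low: float = 4.0,
                        f_high: float = 8.0,
                        grid_max: float = 20.0) -> pd.DataFrame:
    """Peak-to-background ratio of each estimator on the gappy two-tone signal.

    For each removal ratio and seed, random points are deleted from the
    two-tone test signal, each estimator's retention-normalized spectrum is
    computed, and the mean power at the tone frequencies relative to the
    median off-peak power is recorded, together with whether both tones
    remain detectable local maxima.  Returns a tidy frame with columns
    (estimator, ratio, seed, pbr, detected).
    """
    from .preprocess import IncompleteSegment, remove_points
    from .spectral import (fft_periodogram, lsp_spectrum,
                           normalize_power_by_retention, peak_background_ratio,
                           welch_periodogram)
    from .synth import simulate_two_tone

    sig = simulate_two_tone(sampling_rate, duration, amp_ratio, f_low, f_high)
    seg = IncompleteSegment(values=sig.values[None, :],
                            timestamps=sig.timestamps,
                            sampling_rate=sampling_rate,
                            original_length=len(sig.values),
                            label=0, source_trial=0, segment_index=0)
    grid = np.arange(1.0, grid_max + 0.05, 0.1)
    rows = []
    for ri, ratio in enumerate(ratios):
        for seed_i in range(n_seeds):
            spec = RemovalSpec(form="point", proportion=float(ratio),
                               seed=derive_seed(base_seed, ri, seed_i))
            inc = remove_points(seg, spec) if ratio > 0 else seg
            for est in estimators:
                if est == "lsp":
                    sp = lsp_spectrum(inc, grid)
                elif est == "fft":
                    sp = fft_periodogram(inc)
                elif est == "welch":
                    sp = welch_periodogram(inc)
                else:
                    raise ValueError(f"unknown estimator {est!r}")
                sp = normalize_power_by_retention(sp)
                keep = sp.freqs <= grid_max
                sp = replace(sp, freqs=sp.freqs[keep], power=sp.power[:, keep])
                pbr, detected = peak_background_ratio(sp, (f_low, f_high))
                rows.append(dict(estimator=est, ratio=float(ratio),
                                 seed=seed_i, pbr=pbr, detected=detected))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The removal-robustness experiment


@dataclass
class SegmentArrays:
    """All segments of a dataset stacked into dense arrays."""

    values: np.ndarray  # segments x channels x samples (uniform grid)
    labels: np.ndarray
    trial_ids: np.ndarray
    sampling_rate: float

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]


def prepare_segments(trials: Sequence[Trial],
                     filter_spec: Optional[FilterSpec] = FilterSpec(),
                     window_spec: WindowSpec = WindowSpec()) -> SegmentArrays:
    """Band-pass filter (optional) and segment a list of trials into arrays."""
    values, labels, trial_ids = [], [], []
    for trial in trials:
        filtered = bandpass_filter(trial, filter_spec) if filter_spec else trial
        for seg in segment_trial(filtered, window_spec):
            values.append(seg.values)
            labels.append(seg.label)
            trial_ids.append(seg.source_trial)
    return SegmentArrays(values=np.stack(values), labels=np.asarray(labels),
                         trial_ids=np.asarray(trial_ids),
                         sampling_rate=trials[0].sampling_rate)


def removal_masks(segments: SegmentArrays, form: str, proportion: float,
                  removal: RemovalSpec, seed: int) -> np.ndarray:
    """Per-segment keep-masks with per-segment derived seeds."""
    n_seg, _, n = segments.values.shape
    masks = np.ones((n_seg, n), dtype=bool)
    if proportion <= 0:
        return masks
    child_seeds = np.random.SeedSequence(seed).generate_state(n_seg)
    for i in range(n_seg):
        rng = np.random.default_rng(child_seeds[i])
        if form == "point":
            masks[i] = _point_keep_mask(n, proportion, rng)
        elif form == "chunk":
            masks[i] = _chunk_keep_mask(n, proportion, removal.chunk_width_mean,
                                        removal.chunk_width_sd, rng)
        else:
            raise ValueError(f"unknown removal form {form!r}")
    return masks


def features_from_masks(segments: SegmentArrays, masks: np.ndarray,
                        estimator: str,
                        freq_grid: Optional[np.ndarray] = None,
                        bands: SubbandSpec = SubbandSpec()) -> np.ndarray:
    """Retention-normalized band-power features for every segment.

    LSP features come from the vectorized least-squares path on the original
    timestamps; FFT/Welch features treat the retained samples as a uniform
    series at the original rate (concatenation).  All powers are divided by
    the retained fraction before band averaging.
    """
    if freq_grid is None:
        freq_grid = default_freq_grid()
    fs = segments.sampling_rate
    n = segments.n_samples
    if estimator == "lsp":
        power = lsp_spectra_batch(segments.values, masks, fs, freq_grid)
        retained = masks.sum(axis=1) / n
        power = power / retained[:, None, None]
        return subband_features_batch(power, freq_grid, bands)

    # Uniform-grid estimators: group segments by retained length so each
    # group is one batched scipy call.
    from scipy import signal as sps

    counts = masks.sum(axis=1)
    feats = np.empty((segments.n_segments, segments.values.shape[1] * bands.n_bands))
    for count in np.unique(counts):
        idx = np.flatnonzero(counts == count)
        block = np.stack([segments.values[i][:, masks[i]] for i in idx])
        nfft = max(n, int(count))
        if estimator == "fft":
            freqs, power = sps.periodogram(block, fs=fs, detrend=False,
                                           nfft=nfft, axis=-1)
        elif estimator == "welch":
            nperseg = min(int(count), max(32, int(count) // 4))
            freqs, power = sps.welch(block, fs=fs, nperseg=nperseg,
                                     noverlap=nperseg // 2, detrend=False,
                                     nfft=nfft, axis=-1)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        keep = freqs > 0
        power = power[..., keep] / (count / n)
        feats[idx] = subband_features_batch(power, freqs[keep], bands)
    return feats


def _train_eval(estimator: str, classifier: str, X: np.ndarray,
                segments: SegmentArrays, split: Split, seed: int,
                dbn_hidden: Tuple[int, ...], dbn_config: TrainConfig,
                svm_config: SvmConfig, n_classes: int) -> Tuple[float, float]:
    """Fit one pipeline cell; returns (segment accuracy, trial-voted accuracy)."""
    y = segments.labels
    stats = fit_minmax(X[split.train_idx])
    Xtr = apply_minmax(X[split.train_idx], stats)
    Xte = apply_minmax(X[split.test_idx], stats)
    if classifier == "dbn":
        cfg = replace(dbn_config, seed=seed)
        model = fit_dbn(Xtr, y[split.train_idx], dbn_hidden, cfg,
                        class_count=n_classes)
        pred = predict(model, Xte)
    elif classifier == "svm":
        cfg = replace(svm_config, seed=seed)
        committee = train_svm_committee(Xtr, y[split.train_idx], cfg)
        pred = predict_svm(committee, Xte)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    acc = float(np.mean(pred == y[split.test_idx]))
    trials, voted = majority_vote_trial(pred, segments.trial_ids[split.test_idx],
                                        n_classes)
    true_per_trial = np.asarray(
        [segments.labels[segments.trial_ids == t][0] for t in trials])
    acc_trial = float(np.mean(voted == true_per_trial))
    return acc, acc_trial


def run_removal_curve(trials: Sequence[Trial],
                      estimators: Sequence[str] = ("lsp", "fft", "welch"),
                      classifiers: Sequence[str] = ("dbn",),
                      forms: Sequence[str] = ("point", "chunk"),
                      ratios: Sequence[float] = DEFAULT_RATIOS,
                      n_seeds: int = 10,
                      base_seed: int = 0,
                      filter_spec: Optional[FilterSpec] = FilterSpec(),
                      window_spec: WindowSpec = WindowSpec(),
                      removal: RemovalSpec = RemovalSpec(),
                      freq_grid: Optional[np.ndarray] = None,
                      bands: SubbandSpec = SubbandSpec(),
                      split_spec: SplitSpec = SplitSpec(),
                      dbn_hidden: Tuple[int, ...] = (60, 50, 35),
                      dbn_config: TrainConfig = HARNESS_DBN_CONFIG,
                      svm_config: SvmConfig = SvmConfig(),
                      include_intact: bool = True) -> RemovalCurve:
    """Accuracy versus data-removal ratio for every pipeline combination.

    For each seed, removal is applied independently per segment (train and
    test sides alike), features are extracted, min-max normalization is fit
    on the training split only, the classifier is trained and segment-level
    test accuracy recorded (trial-voted accuracy rides along).  Ratio 0
    rows (form "intact") carry the undamaged-pipeline reference.  Every
    random draw derives from ``base_seed``, so the curve is reproducible
    bit for bit.
    """
    segments = prepare_segments(trials, filter_spec, window_spec)
    n_classes = int(segments.labels.max()) + 1
    if freq_grid is None:
        freq_grid = default_freq_grid()

    rows: List[dict] = []
    intact_feats: Dict[str, np.ndarray] = {}
    if include_intact:
        full = np.ones((segments.n_segments, segments.n_samples), dtype=bool)
        for est in estimators:
            intact_feats[est] = features_from_masks(segments, full, est,
                                                    freq_grid, bands)
    for seed_i in range(n_seeds):
        split = split_dataset(
            segments.n_segments, segments.trial_ids,
            replace(split_spec, seed=derive_seed(base_seed, seed_i, 0x5B117)))
        if include_intact:
            for ei, est in enumerate(estimators):
                for ci, clf in enumerate(classifiers):
                    acc, acc_t = _train_eval(
                        est, clf, intact_feats[est], segments, split,
                        derive_seed(base_seed, seed_i, 0, 0, ei, ci),
                        dbn_hidden, dbn_config, svm_config, n_classes)
                    rows.append(dict(form="intact", ratio=0.0, seed=seed_i,
                                     estimator=est, classifier=clf,
                                     accuracy=acc, accuracy_trial=acc_t))
        for fi, form in enumerate(forms):
            for ri, ratio in enumerate(ratios):
                mask_seed = derive_seed(base_seed, seed_i, fi + 1, ri)
                masks = removal_masks(segments, form, ratio, removal, mask_seed)
                for ei, est in enumerate(estimators):
                    X = features_from_masks(segments, masks, est, freq_grid, bands)
                    for ci, clf in enumerate(classifiers):
                        train_seed = derive_seed(base_seed, seed_i, fi + 1, ri,
                                                 ei, ci)
                        acc, acc_t = _train_eval(est, clf, X, segments, split,
                                                 train_seed, dbn_hidden,
                                                 dbn_config, svm_config,
                                                 n_classes)
                        rows.append(dict(form=form, ratio=float(ratio),
                                         seed=seed_i, estimator=est,
                                         classifier=clf, accuracy=acc,
                                         accuracy_trial=acc_t))
    results = pd.DataFrame(rows)
    all_ratios = ((0.0,) if include_intact else ()) + tuple(float(r) for r in ratios)
    return RemovalCurve(results=results, ratios=all_ratios)
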