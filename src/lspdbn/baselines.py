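"""Reference classifier: a committee of binary RBF-kernel SVMs.

For three classes, one binary SVM is trained per unordered class pair
(three machines) and test labels are decided by majority vote, ties going
to the lowest class index.  Each binary machine's regularization C and
kernel width sigma are selected independently by cross-validated grid
search over powers of the grid base (2**-5 .. 2**5 by default); sigma maps
to sklearn's RBF parameter as gamma = 1 / (2 * sigma**2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from ._utils import derive_seed

__all__ = ["SvmConfig", "SvmCommittee", "train_svm_committee", "predict_svm"]


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"
    c_exponents: Tuple[int, ...] = tuple(range(-5, 6))
    gamma_exponents: Tuple[int, ...] = tuple(range(-5, 6))
    grid_base: float = 2.0
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_exponents or not self.gamma_exponents:
            raise ValueError("exponent ranges must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grid_base <= 1:
            raise ValueError("grid_base must exceed 1")


@dataclass
class SvmCommittee:
    """Fitted pairwise machines plus the hyper-parameters they chose."""

    machines: Dict[Tuple[int, int], SVC]
    classes: Tuple[int, ...]
    chosen_params: Dict[Tuple[int, int], Dict[str, float]]
    cv_tables: Dict[Tuple[int, int], np.ndarray]


def _sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma**2)


def train_svm_committee(X: np.ndarray, y: np.ndarray,
                        config: SvmConfig = SvmConfig()) -> SvmCommittee:
    """Fit one grid-searched binary RBF SVM per unordered class pair."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes present in training data")
    machines: Dict[Tuple[int, int], SVC] = {}
    chosen: Dict[Tuple[int, int], Dict[str, float]] = {}
    tables: Dict[Tuple[int, int], np.ndarray] = {}
    for pair in combinations(classes, 2):
        mask = np.isin(y, pair)
        Xp, yp = X[mask], y[mask]
        cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                             random_state=derive_seed(config.seed, *pair))
        scores = np.empty((len(config.c_exponents), len(config.gamma_exponents)))
        for i, ce in enumerate(config.c_exponents):
            for j, ge in enumerate(config.gamma_exponents):
                sigma = config.grid_base**ge
                svc = SVC(C=config.grid_base**ce, kernel=config.kernel,
                          gamma=_sigma_to_gamma(sigma))
                scores[i, j] = cross_val_score(svc, Xp, yp, cv=cv).mean()
        best_flat = int(np.argmax(scores))  # first maximum: deterministic
        bi, bj = np.unravel_index(best_flat, scores.shape)
        C = config.grid_base**config.c_exponents[bi]
        sigma = config.grid_base**config.gamma_exponents[bj]
        svc = SVC(C=C, kernel=config.kernel, gamma=_sigma_to_gamma(sigma))
        svc.fit(Xp, yp)
        machines[pair] = svc
        chosen[pair] = {"C": C, "sigma": sigma, "gamma": _sigma_to_gamma(sigma),
                        "cv_accuracy": float(scores[bi, bj])}
        tables[pair] = scores
    return SvmCommittee(machines=machines, classes=classes,
                        chosen_params=chosen, cv_tables=tables)


def _vote_labels(votes: np.ndarray, n_classes: int) -> np.ndarray:
    """Modal vote per row; ties resolve to the lowest class index."""
    out = np.empty(len(votes), dtype=int)
    for i, row in enumerate(votes):
        out[i] = int(np.argmax(np.bincount(row, minlength=n_classes)))
    return out


def predict_svm(committee: SvmCommittee, X: np.ndarray) -> np.ndarray:
    """Majority vote across the pairwise machines."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    votes = np.stack([m.predict(X) for m in committee.machines.values()], axis=1)
    n_classes = max(committee.classes) + 1
    return _vote_labels(votes.astype(int), n_classes)
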