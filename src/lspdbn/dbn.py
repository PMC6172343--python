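"""Deep belief network classifier built from restricted Boltzmann machines.

An RBM is a bipartite energy model over binary visible/hidden units:

    E(v, h) = - b.v - a.h - v^T W h,      p(v, h) = exp(-E) / Z.

Conditionals factorize: p(h_j=1|v) = sigmoid(a_j + v.W[:,j]) and
symmetrically for visibles.  Training maximizes the data log-likelihood; the
gradient is E_data[v h^T] - E_model[v h^T], with the intractable model term
approximated by k steps of Gibbs sampling started at the data (contrastive
divergence, CD-k).

Three RBMs are pretrained greedily (each upper machine consumes the lower
hidden activation *probabilities*), a softmax output layer is stacked on
top, and the whole network is fine-tuned by backpropagation on a cost of
cross-entropy + L2 weight decay + a KL sparsity penalty that pulls mean
hidden activations toward a target rate.

Visible-unit semantics: first-layer inputs are min-max-scaled features in
[0, 1] treated as activation probabilities (mean-field); hidden units are
sampled as stochastic binaries during CD, but the gradient statistics use
probabilities, which lowers estimator variance without changing its
expectation.

Exact enumeration oracles (`partition_function`, `joint_prob`,
`exact_loglik_grad`) are provided for small machines so the sampled
learning rules can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit, softmax

from ._utils import derive_seed

__all__ = [
    "RBMParams",
    "TrainConfig",
    "DBNModel",
    "TrainingDivergedError",
    "rbm_energy",
    "partition_function",
    "joint_prob",
    "prob_h_given_v",
    "prob_v_given_h",
    "exact_loglik_grad",
    "cd_update",
    "train_rbm",
    "pretrain",
    "finetune",
    "predict_proba",
    "predict",
    "grid_search_structure",
]

_MAX_ENUM_UNITS = 20

#: Coordinate-search ranges for the three hidden layers: each layer sweeps
#: its range while the other two hold their canonical 60/50/35 widths.
DEFAULT_STRUCTURE_GRID = (
    tuple((u, 50, 35) for u in (15, 30, 45, 60, 75, 90))
    + tuple((60, u, 35) for u in (10, 20, 30, 40, 50, 60))
    + tuple((60, 50, u) for u in (25, 30, 35, 50, 70, 85))
)


class TrainingDivergedError(RuntimeError):
    """Raised when parameters or the loss become non-finite during training."""


@dataclass(frozen=True)
class RBMParams:
    """One RBM: weights (visible x hidden) and the two bias vectors."""

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.weights, dtype=float))
        vb = np.asarray(self.visible_bias, dtype=float)
        hb = np.asarray(self.hidden_bias, dtype=float)
        if w.shape != (len(vb), len(hb)):
            raise ValueError("weight matrix and biases disagree on shape")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(vb))
                and np.all(np.isfinite(hb))):
            raise ValueError("RBM parameters must be finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "visible_bias", vb)
        object.__setattr__(self, "hidden_bias", hb)

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters for pre-training and fine-tuning.

    The CD learning rates (0.5 for weights, 0.25 for biases), the weight
    decay 0.05 and the sparsity target 0.1 are the standard operating point
    for this decoder; epochs, batch size and the fine-tuning rate are
    desk-scale choices and freely configurable.
    """

    lr_weights: float = 0.5
    lr_biases: float = 0.25
    weight_decay: float = 0.05
    sparsity_target: float = 0.1
    sparsity_weight: float = 1.0
    cd_steps: int = 1
    pretrain_epochs: int = 50
    finetune_epochs: int = 200
    batch_size: int = 100
    finetune_lr: float = 0.1
    lr_decay: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_weights, self.lr_biases, self.finetune_lr) <= 0:
            raise ValueError("learning rates must be positive")
        if not 0 < self.sparsity_target < 1:
            raise ValueError("sparsity_target must lie in (0, 1)")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")


@dataclass
class DBNModel:
    """Stacked RBMs plus a softmax output layer."""

    rbms: List[RBMParams]
    softmax_weights: np.ndarray
    softmax_bias: np.ndarray
    layer_sizes: Tuple[int, ...]
    class_count: int
    pretrained: bool = False
    finetuned: bool = False
    config: Optional[TrainConfig] = None

    @property
    def n_features(self) -> int:
        return self.layer_sizes[0]


# ---------------------------------------------------------------------------
# Energies, probabilities and exact oracles


def rbm_energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """E(v, h) = -b.v - a.h - v^T W h."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("state shapes do not match the machine")
    return float(-params.visible_bias @ v - params.hidden_bias @ h
                 - v @ params.weights @ h)


def _all_states(n: int) -> np.ndarray:
    """All 2**n binary vectors of length n, one per row."""
    return ((np.arange(2**n)[:, None] >> np.arange(n)[::-1]) & 1).astype(float)


def _check_enumerable(params: RBMParams) -> None:
    if params.n_visible + params.n_hidden > _MAX_ENUM_UNITS:
        raise ValueError(
            f"machine too large to enumerate (> {_MAX_ENUM_UNITS} units)")


def partition_function(params: RBMParams) -> float:
    """Z by exhaustive enumeration; small machines only."""
    _check_enumerable(params)
    V = _all_states(params.n_visible)
    H = _all_states(params.n_hidden)
    energies = (-(V @ params.visible_bias)[:, None]
                - (H @ params.hidden_bias)[None, :]
                - V @ params.weights @ H.T)
    return float(np.exp(-energies).sum())


def joint_prob(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """p(v, h) = exp(-E(v, h)) / Z by enumeration; small machines only."""
    return float(np.exp(-rbm_energy(v, h, params)) / partition_function(params))


def prob_h_given_v(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) = sigmoid(a_j + sum_i v_i w_ij); supports batches."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError("visible state has wrong dimension")
    return expit(params.hidden_bias + v @ params.weights)


def prob_v_given_h(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """p(v_i = 1 | h) = sigmoid(b_i + sum_j h_j w_ij); supports batches."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError("hidden state has wrong dimension")
    return expit(params.visible_bias + h @ params.weights.T)


def exact_loglik_grad(params: RBMParams, data: np.ndarray):
    """Exact gradient of the mean data log-likelihood, by enumeration.

    Returns (dW, db_visible, da_hidden) = E_data[...] - E_model[...], where
    the data term uses the analytic conditionals and the model term sums
    over all joint states.  Only feasible for small machines.
    """
    _check_enumerable(params)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    hp = prob_h_given_v(params, data)
    grad_w_data = data.T @ hp / len(data)
    grad_vb_data = data.mean(axis=0)
    grad_hb_data = hp.mean(axis=0)

    V = _all_states(params.n_visible)
    H = _all_states(params.n_hidden)
    energies = (-(V @ params.visible_bias)[:, None]
                - (H @ params.hidden_bias)[None, :]
                - V @ params.weights @ H.T)
    p = np.exp(-energies)
    p /= p.sum()
    grad_w_model = V.T @ p @ H
    grad_vb_model = p.sum(axis=1) @ V
    grad_hb_model = p.sum(axis=0) @ H
    return (grad_w_data - grad_w_model,
            grad_vb_data - grad_vb_model,
            grad_hb_data - grad_hb_model)


# ---------------------------------------------------------------------------
# Contrastive-divergence pre-training


def cd_update(params: RBMParams, batch: np.ndarray, config: TrainConfig,
              rng: Optional[np.random.Generator] = None) -> RBMParams:
    """One CD-k parameter update on a batch of visible vectors in [0, 1].

    Positive phase clamps the data and uses hidden probabilities; the
    negative phase runs k Gibbs steps with sampled binary hidden states and
    mean-field real-valued visibles.  Weights move with ``lr_weights``,
    both bias vectors with ``lr_biases``.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("batch must be non-empty")
    if batch.shape[1] != params.n_visible:
        raise ValueError("batch dimension does not match the machine")
    if np.any((batch < 0) | (batch > 1)):
        raise ValueError("visible values must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(batch)

    h0p = prob_h_given_v(params, batch)
    h = (rng.random(h0p.shape) < h0p).astype(float)
    vk = batch
    for step in range(config.cd_steps):
        vk = prob_v_given_h(params, h)
        hkp = prob_h_given_v(params, vk)
        if step < config.cd_steps - 1:
            h = (rng.random(hkp.shape) < hkp).astype(float)

    dw = (batch.T @ h0p - vk.T @ hkp) / n
    dvb = (batch - vk).mean(axis=0)
    dhb = (h0p - hkp).mean(axis=0)

    new = RBMParams(
        weights=params.weights + config.lr_weights * dw,
        visible_bias=params.visible_bias + config.lr_biases * dvb,
        hidden_bias=params.hidden_bias + config.lr_biases * dhb,
    )
    return new


def _init_rbm(n_visible: int, n_hidden: int, rng: np.random.Generator) -> RBMParams:
    return RBMParams(weights=rng.normal(0.0, 0.01, size=(n_visible, n_hidden)),
                     visible_bias=np.zeros(n_visible),
                     hidden_bias=np.zeros(n_hidden))


def train_rbm(data: np.ndarray, n_hidden: int, config: TrainConfig,
              rng: np.random.Generator) -> Tuple[RBMParams, List[float]]:
    """CD-train one RBM; returns parameters and per-epoch reconstruction MSE."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    params = _init_rbm(data.shape[1], n_hidden, rng)
    history: List[float] = []
    n = len(data)
    batch = min(config.batch_size, n)
    for _ in range(config.pretrain_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch):
            idx = order[lo:lo + batch]
            try:
                params = cd_update(params, data[idx], config, rng)
            except ValueError as exc:  # finiteness check inside RBMParams
                raise TrainingDivergedError(str(exc)) from exc
        recon = prob_v_given_h(params, prob_h_given_v(params, data))
        history.append(float(np.mean((data - recon) ** 2)))
    return params, history


def pretrain(layer_sizes: Sequence[int], data: np.ndarray,
             config: TrainConfig, class_count: int = 3) -> DBNModel:
    """Greedy bottom-up pre-training of the RBM stack.

    ``layer_sizes`` lists the visible dimension followed by the hidden layer
    widths (the canonical decoder is 256 -> 60 -> 50 -> 35).  Each upper RBM
    is trained on the lower machine's hidden activation probabilities.  The
    softmax output layer is initialized small and random; with
    ``pretrain_epochs == 0`` the seeded random initialization is returned
    unchanged.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if data.shape[1] != layer_sizes[0]:
        raise ValueError("data dimension does not match the first layer size")
    rng = np.random.default_rng(config.seed)
    rbms: List[RBMParams] = []
    activations = data
    for n_vis, n_hid in zip(layer_sizes[:-1], layer_sizes[1:]):
        if activations.shape[1] != n_vis:
            raise ValueError("layer dimension chain is broken")
        if config.pretrain_epochs == 0:
            params = _init_rbm(n_vis, n_hid, rng)
        else:
            params, _ = train_rbm(activations, n_hid, config, rng)
        rbms.append(params)
        activations = prob_h_given_v(params, activations)
    softmax_w = rng.normal(0.0, 0.01, size=(layer_sizes[-1], class_count))
    return DBNModel(rbms=rbms, softmax_weights=softmax_w,
                    softmax_bias=np.zeros(class_count),
                    layer_sizes=layer_sizes, class_count=class_count,
                    pretrained=config.pretrain_epochs > 0, config=config)


# ---------------------------------------------------------------------------
# Supervised fine-tuning


def _forward(model: DBNModel, X: np.ndarray) -> List[np.ndarray]:
    """Deterministic forward pass; returns [input, hidden1, ..., probs]."""
    acts = [X]
    a = X
    for rbm in model.rbms:
        a = expit(rbm.hidden_bias + a @ rbm.weights)
        acts.append(a)
    logits = model.softmax_bias + a @ model.softmax_weights
    acts.append(softmax(logits, axis=1))
    return acts


def _loss_and_grads(model: DBNModel, X: np.ndarray, y: np.ndarray,
                    config: TrainConfig):
    """Cost and full-network gradients for fine-tuning.

    Cost = mean cross-entropy
         + (weight_decay / 2) * sum of squared softmax connection weights
         + sparsity_weight * sum over hidden layers of the per-unit mean
             KL(sparsity_target || mean activation).

    The decay term regularizes the softmax output layer (where the
    constraints enter the classification cost); the sparsity penalty is
    normalized per hidden unit so its pull does not grow with network
    width.  Biases are not decayed.
    """
    n = len(X)
    lam = config.weight_decay
    rho = config.sparsity_target
    beta = config.sparsity_weight
    eps = 1e-8

    acts = _forward(model, X)
    probs = acts[-1]
    hidden = acts[1:-1]
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0

    ce = -np.mean(np.log(probs[np.arange(n), y] + eps))
    l2 = 0.5 * lam * np.sum(model.softmax_weights**2)
    rho_hat = [np.clip(h.mean(axis=0), eps, 1 - eps) for h in hidden]
    kl = sum(np.mean(rho * np.log(rho / rh)
                     + (1 - rho) * np.log((1 - rho) / (1 - rh)))
             for rh in rho_hat)
    loss = ce + l2 + beta * kl

    # Backward pass.
    delta = (probs - onehot) / n  # d loss / d logits
    g_sw = hidden[-1].T @ delta + lam * model.softmax_weights
    g_sb = delta.sum(axis=0)
    g_rbm = []
    delta = delta @ model.softmax_weights.T
    for li in range(len(model.rbms) - 1, -1, -1):
        h = hidden[li]
        # Sparsity pulls the mean activation of each unit toward rho.
        sparsity_term = beta * (-rho / rho_hat[li]
                                + (1 - rho) / (1 - rho_hat[li])) / (n * h.shape[1])
        delta = (delta + sparsity_term) * h * (1 - h)
        below = acts[li]
        g_w = below.T @ delta
        g_hb = delta.sum(axis=0)
        g_rbm.append((g_w, g_hb))
        delta = delta @ model.rbms[li].weights.T
    g_rbm.reverse()
    return loss, g_rbm, g_sw, g_sb


def finetune(model: DBNModel, X: np.ndarray, y: np.ndarray,
             config: Optional[TrainConfig] = None) -> DBNModel:
    """Backpropagation fine-tuning of the whole stack plus softmax layer.

    Mini-batch SGD with a geometrically decaying learning rate; returns a
    new model (the input is not modified).  Raises
    :class:`TrainingDivergedError` if the loss becomes non-finite.
    """
    if config is None:
        config = model.config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimension does not match the model")
    rng = np.random.default_rng(derive_seed(config.seed, 0xF1FE))
    rbms = [RBMParams(r.weights.copy(), r.visible_bias.copy(),
                      r.hidden_bias.copy()) for r in model.rbms]
    work = DBNModel(rbms=rbms, softmax_weights=model.softmax_weights.copy(),
                    softmax_bias=model.softmax_bias.copy(),
                    layer_sizes=model.layer_sizes,
                    class_count=model.class_count,
                    pretrained=model.pretrained, config=config)
    n = len(X)
    batch = min(config.batch_size, n)
    lr = config.finetune_lr
    history: List[float] = []
    for _ in range(config.finetune_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for lo in range(0, n, batch):
            idx = order[lo:lo + batch]
            loss, g_rbm, g_sw, g_sb = _loss_and_grads(work, X[idx], y[idx], config)
            if not np.isfinite(loss):
                raise TrainingDivergedError("fine-tuning loss became non-finite")
            batch_losses.append(loss)
            for li, (g_w, g_hb) in enumerate(g_rbm):
                r = work.rbms[li]
                work.rbms[li] = RBMParams(r.weights - lr * g_w,
                                          r.visible_bias,
                                          r.hidden_bias - lr * g_hb)
            work.softmax_weights -= lr * g_sw
            work.softmax_bias -= lr * g_sb
        history.append(float(np.mean(batch_losses)))
        lr *= config.lr_decay
    work.finetuned = True
    work.loss_history = history  # type: ignore[attr-defined]
    return work


def predict_proba(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities from the deterministic forward pass."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError("feature dimension does not match the model")
    return _forward(model, X)[-1]


def predict(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Hard labels; ties resolve to the lowest class index."""
    return np.argmax(predict_proba(model, X), axis=1)


def fit_dbn(X: np.ndarray, y: np.ndarray, hidden_sizes: Sequence[int],
            config: TrainConfig, class_count: Optional[int] = None) -> DBNModel:
    """Convenience: pretrain then fine-tune in one call."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if class_count is None:
        class_count = int(np.max(y)) + 1
    layer_sizes = (X.shape[1], *hidden_sizes)
    model = pretrain(layer_sizes, X, config, class_count=class_count)
    return finetune(model, X, y, config)


def grid_search_structure(X: np.ndarray, y: np.ndarray,
                          candidate_unit_lists: Optional[Sequence[Tuple[int, int, int]]] = None,
                          k: int = 5, seed: int = 0,
                          config: Optional[TrainConfig] = None):
    """Coordinate search over hidden-layer widths with k-fold CV.

    With no explicit candidates, each hidden layer in turn sweeps its
    standard range ([15..90], [10..60], [25..85]) while the other two stay
    at the canonical 60/50/35 values.  Returns (best_sizes, table) where the
    table lists mean CV accuracy per candidate.
    """
    import pandas as pd

    from .evaluate import kfold_indices

    if candidate_unit_lists is None:
        candidate_unit_lists = DEFAULT_STRUCTURE_GRID
    if len(candidate_unit_lists) == 0:
        raise ValueError("candidate list must be non-empty")
    if config is None:
        config = TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    folds = kfold_indices(len(X), k=k, seed=seed)
    rows = []
    for sizes in candidate_unit_lists:
        accs = []
        for fold in range(k):
            test = folds == fold
            cfg = replace(config, seed=derive_seed(seed, fold, *sizes))
            model = fit_dbn(X[~test], y[~test], sizes, cfg)
            accs.append(float(np.mean(predict(model, X[test]) == y[test])))
        rows.append({"hidden_sizes": tuple(sizes),
                     "mean_cv_accuracy": float(np.mean(accs)),
                     "sd_cv_accuracy": float(np.std(accs))})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_cv_accuracy"].idxmax(), "hidden_sizes"]
    return tuple(best), table
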