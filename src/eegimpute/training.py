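"""Optimization loop: Adam, self-supervised hold-out masking, early stopping.

Training is self-supervised: each batch additionally hides a fraction of the
*observed* cells (so their true values are known), and the loss is the mean
squared estimate error on exactly those held-out cells. The validation split
uses a hold-out masking fixed once per run so "lowest validation error" is a
consistent target across epochs; the returned weights are the ones from the
best validation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EEGTrialSet
from .model import (
    ModelConfig,
    ModelParams,
    _conv_pool,
    init_params,
    loss_and_grads,
    montage_fingerprint,
)
from .montage import Montage, pairwise_distance

__all__ = ["TrainConfig", "split_validation", "apply_ablation", "train"]

_ABLATIONS = {
    "full": (True, True),
    "no_state": (False, True),
    "no_space": (True, False),
    "no_state_space": (False, False),
}


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    lambda_mix: float = 0.8
    val_fraction: float = 0.15
    patience: int = 10
    max_epochs: int = 300
    seed: int = 0
    hold_out_rate: float = 0.10
    ablation: str = "full"
    hidden_size: int = 32
    state_encoder: str = "label"
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must be in [0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.hold_out_rate < 1.0:
            raise ValueError("hold_out_rate must be in (0, 1)")
        if self.ablation not in _ABLATIONS:
            raise ValueError(
                f"unknown ablation {self.ablation!r}; choose from {sorted(_ABLATIONS)}"
            )


def apply_ablation(config: TrainConfig) -> tuple[bool, bool]:
    """Structural switches (use_state, use_space) for the configured arm.

    ``no_space`` removes the spatial gate entirely and forces the mixing
    weight to zero; ``no_state`` drops the state vector (zero-length
    concatenation); ``no_state_space`` leaves exactly the mask+temporal-decay
    backbone.
    """
    return _ABLATIONS[config.ablation]


def split_validation(dataset: EEGTrialSet, fraction: float, seed: int):
    """Disjoint, exhaustive train/validation split, deterministic given seed."""
    n = dataset.n_trials
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    n_val = int(round(fraction * n))
    if n_val == 0 or n_val == n:
        raise ValueError(f"fraction {fraction} leaves an empty split for {n} trials")
    perm = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B])).permutation(n)
    return dataset.subset(np.sort(perm[n_val:])), dataset.subset(np.sort(perm[:n_val]))


def _hold_out(xn: np.ndarray, rng: np.random.Generator, rate: float):
    """Hide `rate` of observed cells per trial; returns (x_in, m_in, score).

    At least one cell per trial is always held so every trial contributes to
    the loss.
    """
    B, T, D = xn.shape
    observed = np.isfinite(xn)
    score = np.zeros((B, T, D))
    for i in range(B):
        idx = np.flatnonzero(observed[i].ravel())
        k = max(int(np.floor(rate * idx.size)), 1)
        chosen = rng.choice(idx, size=k, replace=False)
        score[i].ravel()[chosen] = 1.0
    m_in = observed.astype(np.float64) * (1.0 - score)
    x_in = np.where(m_in > 0, np.nan_to_num(xn, nan=0.0), 0.0)
    return x_in, m_in, score


class _Adam:
    def __init__(self, arrays, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}

    def step(self, arrays, grads):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            arrays[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _clip(grads, max_norm):
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def _state_inputs(params: ModelParams, xn_in, labels):
    """Batch state vectors plus the gradient-routing payload."""
    cfg = params.config
    if not cfg.use_state:
        return None, None
    if cfg.state_encoder == "label":
        y = params.arrays["embed"][labels]
        return y, ("embed", labels)
    if cfg.state_encoder == "conv":
        z = _conv_pool(xn_in, cfg.n_conv_bins)
        y = np.tanh(z @ params.arrays["W_enc"].T + params.arrays["b_enc"])
        return y, ("conv", z)
    raise ValueError("external state encoding is not trainable inside train()")


def _epoch_losses(split_x, labels, params, rng, rate, batch_size, opt=None, clip=5.0):
    """One sweep over a split; optimizes in place when `opt` is given."""
    n = split_x.shape[0]
    order = rng.permutation(n) if opt is not None else np.arange(n)
    total, cells = 0.0, 0
    for start in range(0, n, batch_size):
        take = order[start : start + batch_size]
        xb = split_x[take]
        x_in, m_in, score = _hold_out(xb, rng, rate)
        target = np.nan_to_num(xb, nan=0.0)
        y, route = _state_inputs(params, x_in, None if labels is None else labels[take])
        loss, grads = loss_and_grads(x_in, m_in, target, score, params, y=y, y_backprop=route)
        if opt is not None:
            _clip(grads, clip)
            opt.step(params.arrays, grads)
        k = int(score.sum())
        total += loss * k
        cells += k
    return total / cells


def train(dataset: EEGTrialSet, montage: Montage, config: TrainConfig):
    """Fit the imputer; returns (best-epoch ModelParams, per-epoch history).

    History entries are ``{"epoch", "train_loss", "val_loss", "best_so_far"}``
    with losses in normalized (z-scored) units. Fully seeded: identical
    dataset + config reproduce identical histories.
    """
    if dataset.n_trials == 0:
        raise ValueError("empty dataset")
    if list(montage.channel_names) != list(dataset.channel_names):
        raise ValueError("montage channel order does not match the dataset")
    use_state, use_space = apply_ablation(config)
    if use_state and config.state_encoder == "label" and dataset.labels is None:
        raise ValueError("state-conditioned training requires trial labels")

    train_set, val_set = split_validation(dataset, config.val_fraction, config.seed)

    # Per-channel z-scoring from the observed cells of the training split.
    obs = np.isfinite(train_set.values)
    mu = np.array([train_set.values[..., d][obs[..., d]].mean() for d in range(dataset.n_channels)])
    sd = np.array([train_set.values[..., d][obs[..., d]].std() for d in range(dataset.n_channels)])
    sd = np.where(sd > 1e-12, sd, 1.0)

    n_classes = 0 if dataset.labels is None else int(dataset.labels.max()) + 1
    mcfg = ModelConfig(
        n_channels=dataset.n_channels,
        hidden_size=config.hidden_size,
        lambda_mix=config.lambda_mix if use_space else 0.0,
        use_space=use_space,
        use_state=use_state,
        state_encoder=config.state_encoder,
        n_classes=n_classes,
    )
    params = init_params(mcfg, seed=config.seed)
    params.norm_mu, params.norm_sd = mu, sd
    params.distances = pairwise_distance(montage) if use_space else None
    params.montage_hash = montage_fingerprint(montage.coords)

    xtr = (train_set.values - mu) / sd
    xva = (val_set.values - mu) / sd

    opt = _Adam(params.arrays, config.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_arrays = params.copy_arrays()
    since_best = 0
    for epoch in range(config.max_epochs):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, epoch]))
        train_loss = _epoch_losses(
            xtr, train_set.labels, params, rng, config.hold_out_rate,
            config.batch_size, opt=opt, clip=config.grad_clip,
        )
        # Fixed validation masking: same rng state every epoch.
        vrng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        val_loss = _epoch_losses(
            xva, val_set.labels, params, vrng, config.hold_out_rate, config.batch_size,
        )
        improved = val_loss < best_val
        if improved:
            best_val = val_loss
            best_arrays = params.copy_arrays()
            since_best = 0
        else:
            since_best += 1
        history.append(
            {"epoch": epoch, "train_loss": float(train_loss),
             "val_loss": float(val_loss), "best_so_far": float(best_val)}
        )
        if since_best >= config.patience:
            break
    params.arrays = best_arrays
    return params, history
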