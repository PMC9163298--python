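"""Bidirectional recurrent imputation network with temporal/spatial decay gates.

The imputer is a masked bidirectional recurrence over a trial. At every step
the previous hidden state is discounted elementwise by a combined decay factor

    gamma_t = beta_t + lambda * eta_t,
    beta_t  = exp(-max(0, W_beta delta^t_t + b_beta))   (temporal gaps)
    eta_t   = exp(-max(0, W_eta  delta^d_t + b_eta))    (electrode distances)

where ``delta^t_t`` is the per-channel time-since-last-observation vector and
``delta^d_t`` is a per-step spatial summary: the mean distance profile of the
channels that are currently missing (the channels that must borrow from their
neighbors). The discounted history is projected to a per-channel estimate
``xhat_t``; observed channels keep their recorded value and missing channels
take the estimate (masked input filling), the result is concatenated with a
per-trial state vector ``y`` and drives a tanh recurrence. The backward
direction runs the same machinery on the time-reversed trial with its own
weights, and the final estimate is the arithmetic mean of the two directions.

Because the estimate at step t is produced from *discounted history only*,
no cell ever sees its own-step target. Training minimizes the mean squared
error of the estimates at masked cells against held-out ground truth; all
gradients here are hand-derived (reverse-mode through the recurrence) and are
verified against finite differences in the test suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from .masking import MaskedTrial, compute_temporal_decay

__all__ = [
    "ModelConfig",
    "ModelParams",
    "StateVector",
    "ImputationResult",
    "init_params",
    "temporal_decay_factor",
    "spatial_decay_factor",
    "combine_decay",
    "fill_input",
    "spatial_summary",
    "encode_state",
    "directional_pass",
    "bidirectional_impute",
    "mse_loss",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    n_channels: int
    hidden_size: int = 32
    lambda_mix: float = 0.8
    use_space: bool = True
    use_state: bool = True
    state_encoder: str = "label"  # "label" | "conv" | "external"
    state_dim: int = 0
    n_classes: int = 0
    n_conv_bins: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must be in [0, 1]")
        if self.state_encoder not in ("label", "conv", "external"):
            raise ValueError(f"unknown state encoder {self.state_encoder!r}")
        if not self.use_state:
            self.state_dim = 0
        elif self.state_dim == 0:
            self.state_dim = self.n_classes if self.state_encoder == "label" else 8
        if self.use_state and self.state_encoder == "label" and self.n_classes < 1:
            raise ValueError("label state encoder needs n_classes >= 1")


@dataclass
class ModelParams:
    """All learnable weights plus the frozen artifacts a fit carries along."""

    config: ModelConfig
    arrays: dict[str, np.ndarray]
    norm_mu: np.ndarray | None = None  # per-channel normalization, training split
    norm_sd: np.ndarray | None = None
    distances: np.ndarray | None = None  # (D, D) electrode distance matrix
    montage_hash: str | None = None

    def copy_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.arrays.items()}

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.arrays.values()))


@dataclass
class StateVector:
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        if not np.isfinite(self.y).all():
            raise ValueError("state vector must be finite")


@dataclass
class ImputationResult:
    completed: np.ndarray  # observed values kept, masked cells imputed
    estimates: np.ndarray  # raw model output at every cell
    mask: np.ndarray


def init_params(config: ModelConfig, seed: int = 0) -> ModelParams:
    """Seeded weight initialization (uniform +-1/sqrt(H); small for the gates)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11]))
    H, D, S = config.hidden_size, config.n_channels, config.state_dim
    k = 1.0 / np.sqrt(H)

    def u(*shape, scale=k):
        return rng.uniform(-scale, scale, size=shape)

    arrays: dict[str, np.ndarray] = {
        "W_beta": u(H, D, scale=0.05),
        "b_beta": np.zeros(H),
    }
    if config.use_space:
        arrays["W_eta"] = u(H, D, scale=0.05)
        arrays["b_eta"] = np.zeros(H)
    for p in ("fwd_", "bwd_"):
        arrays[p + "W_xh"] = u(H, D + S)
        arrays[p + "W_hh"] = u(H, H)
        arrays[p + "b_h"] = np.zeros(H)
        arrays[p + "W_x"] = u(D, H)
        arrays[p + "b_x"] = np.zeros(D)
    if config.use_state:
        if config.state_encoder == "label":
            arrays["embed"] = u(config.n_classes, S, scale=0.5)
        elif config.state_encoder == "conv":
            arrays["W_enc"] = u(S, config.n_conv_bins * D, scale=0.1)
            arrays["b_enc"] = np.zeros(S)
    return ModelParams(config=config, arrays=arrays)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def _gate(inp: np.ndarray, W: np.ndarray, b: np.ndarray):
    """exp(-relu(W x + b)); returns (factor, pre-activation). Factor in (0, 1]."""
    z = inp @ W.T + b
    return np.exp(-np.maximum(z, 0.0)), z


def temporal_decay_factor(delta_t: np.ndarray, params: ModelParams) -> np.ndarray:
    """Temporal gate ``beta = exp(-max(0, W_beta delta + b_beta))``."""
    return _gate(np.asarray(delta_t, float), params.arrays["W_beta"], params.arrays["b_beta"])[0]


def spatial_decay_factor(distance_profile: np.ndarray, params: ModelParams) -> np.ndarray:
    """Spatial gate ``eta = exp(-max(0, W_eta delta_d + b_eta))``."""
    if "W_eta" not in params.arrays:
        raise ValueError("model was built without a spatial gate")
    return _gate(np.asarray(distance_profile, float), params.arrays["W_eta"], params.arrays["b_eta"])[0]


def combine_decay(beta: np.ndarray, eta: np.ndarray, lam: float) -> np.ndarray:
    """Combined discount ``gamma = beta + lambda * eta`` (lambda in [0, 1])."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    beta, eta = np.asarray(beta, float), np.asarray(eta, float)
    if beta.shape != eta.shape:
        raise ValueError("beta and eta shapes must agree")
    return beta + lam * eta


def fill_input(x_t: np.ndarray, m_t: np.ndarray, x_hat_t: np.ndarray) -> np.ndarray:
    """Masked complement ``m*x + (1-m)*xhat``: keep observations, fill the rest."""
    x_t, m_t, x_hat_t = (np.asarray(a, float) for a in (x_t, m_t, x_hat_t))
    if (~np.isfinite(x_t) & (m_t == 1)).any():
        raise ValueError("NaN at an observed position")
    if not np.isfinite(x_hat_t).all():
        raise ValueError("estimates must be finite")
    return np.where(m_t == 1, x_t, x_hat_t)


def spatial_summary(mask: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Per-step spatial profile: mean distance row of the currently missing channels.

    Missing channels are the ones that must be reconstructed from neighbors,
    so their distance profiles define how far the useful context sits. Steps
    with nothing missing yield the zero profile (gate argument 0, no discount).
    """
    missing = 1.0 - np.asarray(mask, float)
    num = missing @ np.asarray(distances, float)
    cnt = missing.sum(axis=-1, keepdims=True)
    return num / np.maximum(cnt, 1.0)


def mse_loss(values, estimates, mask, ground_truth) -> float:
    """Mean squared estimate error over masked cells, against held-out truth.

    Returns 0 when the mask is all ones (nothing to score).
    """
    mask = np.asarray(mask, float)
    estimates = np.asarray(estimates, float)
    scored = mask == 0
    if not scored.any():
        return 0.0
    if ground_truth is None:
        raise ValueError("ground truth required at masked positions")
    ground_truth = np.asarray(ground_truth, float)
    if not np.isfinite(ground_truth[scored]).all():
        raise ValueError("ground truth must be finite at masked positions")
    diff = ground_truth[scored] - estimates[scored]
    return float(np.mean(diff**2))


# ---------------------------------------------------------------------------
# State encoding
# ---------------------------------------------------------------------------

def encode_state(trial_or_label, params: ModelParams) -> StateVector:
    """Per-trial state vector under the configured encoder.

    - ``label``: row of a learned embedding table (identity table => one-hot).
    - ``conv``: time-binned average of the observed trial, linearly projected
      and squashed — a lightweight stand-in for a learned trial-feature
      extractor; any richer per-trial feature can be supplied externally.
    - ``external``: pass-through of a user-supplied vector (length-checked).
    """
    cfg = params.config
    if not cfg.use_state:
        return StateVector(np.zeros(0))
    if cfg.state_encoder == "label":
        if trial_or_label is None:
            raise ValueError("label state encoder requires a trial label")
        return StateVector(params.arrays["embed"][int(trial_or_label)])
    if cfg.state_encoder == "external":
        v = np.asarray(trial_or_label, float).ravel()
        if v.size != cfg.state_dim:
            raise ValueError(f"external state vector must have length {cfg.state_dim}")
        return StateVector(v)
    z = _conv_pool(np.asarray(trial_or_label, float)[None], cfg.n_conv_bins)[0]
    return StateVector(np.tanh(params.arrays["W_enc"] @ z + params.arrays["b_enc"]))


def _conv_pool(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a (B, T, D) batch into (B, n_bins*D); NaNs contribute zero."""
    B, T, D = x.shape
    x = np.nan_to_num(x, nan=0.0)
    edges = np.linspace(0, T, n_bins + 1).astype(int)
    pooled = np.stack([x[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])], axis=1)
    return pooled.reshape(B, n_bins * D)


# ---------------------------------------------------------------------------
# Recurrence: batched forward pass and hand-derived reverse-mode gradients
# ---------------------------------------------------------------------------

def _run_direction(xv, m, delta, sprof, y, params: ModelParams, prefix: str) -> dict:
    """One direction over a (B, T, D) batch. ``xv`` must be finite (NaN -> 0).

    Returns a cache with per-step hidden states, discounted states, estimates
    and gate internals, as needed by :func:`_backprop_direction`.
    """
    A, cfg = params.arrays, params.config
    B, T, D = xv.shape
    H = cfg.hidden_size
    beta, zb = _gate(delta, A["W_beta"], A["b_beta"])
    if cfg.use_space:
        eta, ze = _gate(sprof, A["W_eta"], A["b_eta"])
        gam = beta + cfg.lambda_mix * eta
    else:
        eta = ze = None
        gam = beta
    Wxh, Whh, bh = A[prefix + "W_xh"], A[prefix + "W_hh"], A[prefix + "b_h"]
    Wx, bx = A[prefix + "W_x"], A[prefix + "b_x"]
    with_state = y is not None and y.shape[1] > 0

    h = np.zeros((B, H))
    hs = np.empty((B, T, H))
    hds = np.empty((B, T, H))
    xhat = np.empty((B, T, D))
    xcs = np.empty((B, T, D))
    for t in range(T):
        hd = h * gam[:, t]
        xh = hd @ Wx.T + bx
        xc = np.where(m[:, t] > 0, xv[:, t], xh)
        u = np.concatenate([xc, y], axis=1) if with_state else xc
        h = np.tanh(u @ Wxh.T + hd @ Whh.T + bh)
        hds[:, t], xhat[:, t], xcs[:, t], hs[:, t] = hd, xh, xc, h
    if not np.isfinite(hs).all():
        raise FloatingPointError("non-finite hidden state in recurrence")
    return {"h": hs, "hd": hds, "xhat": xhat, "xc": xcs,
            "beta": beta, "zb": zb, "eta": eta, "ze": ze, "gam": gam}


def _backprop_direction(dxhat_ext, cache, xv, m, delta, sprof, y,
                        params: ModelParams, prefix: str, grads, dy):
    """Accumulate parameter gradients for one direction into ``grads``/``dy``."""
    A, cfg = params.arrays, params.config
    B, T, D = xv.shape
    H = cfg.hidden_size
    Wxh, Whh = A[prefix + "W_xh"], A[prefix + "W_hh"]
    Wx = A[prefix + "W_x"]
    with_state = y is not None and y.shape[1] > 0

    dh = np.zeros((B, H))
    dgam = np.empty((B, T, H))
    for t in range(T - 1, -1, -1):
        h_t = cache["h"][:, t]
        hd = cache["hd"][:, t]
        da = dh * (1.0 - h_t**2)
        u = np.concatenate([cache["xc"][:, t], y], axis=1) if with_state else cache["xc"][:, t]
        grads[prefix + "W_xh"] += da.T @ u
        grads[prefix + "b_h"] += da.sum(0)
        grads[prefix + "W_hh"] += da.T @ hd
        du = da @ Wxh
        dhd = da @ Whh
        dxc = du[:, :D]
        if with_state:
            dy += du[:, D:]
        dxh = dxhat_ext[:, t] + np.where(m[:, t] > 0, 0.0, dxc)
        grads[prefix + "W_x"] += dxh.T @ hd
        grads[prefix + "b_x"] += dxh.sum(0)
        dhd += dxh @ Wx
        hprev = cache["h"][:, t - 1] if t > 0 else np.zeros((B, H))
        dgam[:, t] = dhd * hprev
        dh = dhd * cache["gam"][:, t]

    dzb = dgam * (-cache["beta"]) * (cache["zb"] > 0)
    grads["W_beta"] += np.einsum("bth,btd->hd", dzb, delta)
    grads["b_beta"] += dzb.sum((0, 1))
    if cfg.use_space:
        dze = (cfg.lambda_mix * dgam) * (-cache["eta"]) * (cache["ze"] > 0)
        grads["W_eta"] += np.einsum("bth,btd->hd", dze, sprof)
        grads["b_eta"] += dze.sum((0, 1))


def batch_estimates(xv, m, params: ModelParams, y=None, return_caches=False):
    """Bidirectional estimates for a finite (B, T, D) batch.

    The backward direction is realized as the forward recurrence on the
    time-reversed batch (with the temporal decay recomputed on the reversed
    mask) using its own weight set, read back in reverse.
    """
    delta_f = compute_temporal_decay(m)
    sprof = (
        spatial_summary(m, params.distances)
        if params.config.use_space
        else np.zeros_like(m)
    )
    xr = np.ascontiguousarray(xv[:, ::-1])
    mr = np.ascontiguousarray(m[:, ::-1])
    delta_b = compute_temporal_decay(mr)
    sprof_r = np.ascontiguousarray(sprof[:, ::-1])

    cache_f = _run_direction(xv, m, delta_f, sprof, y, params, "fwd_")
    cache_b = _run_direction(xr, mr, delta_b, sprof_r, y, params, "bwd_")
    est = 0.5 * (cache_f["xhat"] + cache_b["xhat"][:, ::-1])
    if return_caches:
        aux = {"delta_f": delta_f, "delta_b": delta_b, "sprof": sprof,
               "sprof_r": sprof_r, "xr": xr, "mr": mr}
        return est, cache_f, cache_b, aux
    return est


def loss_and_grads(xv, m, target, score, params: ModelParams,
                   y=None, y_backprop=None):
    """MSE over scored cells and gradients for every parameter array.

    ``score`` is the binary matrix of held-out cells (1 = scored); ``target``
    must be finite there. ``y_backprop`` optionally routes the state-vector
    gradient into the encoder: ("embed", labels) or ("conv", pooled_input).
    """
    est, cache_f, cache_b, aux = batch_estimates(xv, m, params, y, return_caches=True)
    n = score.sum()
    if n == 0:
        raise ValueError("no scored cells in batch")
    resid = (est - target) * score
    loss = float((resid**2).sum() / n)

    grads = {k: np.zeros_like(v) for k, v in params.arrays.items()}
    S = params.config.state_dim
    dy = np.zeros((xv.shape[0], S)) if S else None
    dest = 2.0 * resid / n
    _backprop_direction(0.5 * dest, cache_f, xv, m, aux["delta_f"], aux["sprof"],
                        y, params, "fwd_", grads, dy)
    _backprop_direction(np.ascontiguousarray(0.5 * dest[:, ::-1]), cache_b,
                        aux["xr"], aux["mr"], aux["delta_b"], aux["sprof_r"],
                        y, params, "bwd_", grads, dy)
    if S and y_backprop is not None:
        kind, payload = y_backprop
        if kind == "embed":
            np.add.at(grads["embed"], payload, dy)
        elif kind == "conv":
            dpre = dy * (1.0 - y**2)
            grads["W_enc"] += dpre.T @ payload
            grads["b_enc"] += dpre.sum(0)
    return loss, grads


# ---------------------------------------------------------------------------
# Public trial-level interface
# ---------------------------------------------------------------------------

def _state_array(state, B: int, cfg: ModelConfig):
    if not cfg.use_state or cfg.state_dim == 0:
        return None
    if state is None:
        raise ValueError("model is state-conditioned but no state vector was given")
    y = state.y if isinstance(state, StateVector) else np.asarray(state, float).ravel()
    if y.size != cfg.state_dim:
        raise ValueError(f"state vector must have length {cfg.state_dim}")
    return np.tile(y, (B, 1))


def directional_pass(masked_trial: MaskedTrial, state, params: ModelParams,
                     direction: str = "forward"):
    """Hidden states and per-step estimates of one direction, in trial time order.

    Operates on the trial values as given (no normalization applied), so
    hand-constructed weights act on the raw numbers.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    m = masked_trial.mask[None]
    xv = np.nan_to_num(masked_trial.values, nan=0.0)[None]
    y = _state_array(state, 1, params.config)
    sprof = (
        spatial_summary(m, params.distances)
        if params.config.use_space
        else np.zeros_like(m)
    )
    if direction == "forward":
        cache = _run_direction(xv, m, compute_temporal_decay(m), sprof, y, params, "fwd_")
        return cache["h"][0], cache["xhat"][0]
    xr = np.ascontiguousarray(xv[:, ::-1])
    mr = np.ascontiguousarray(m[:, ::-1])
    cache = _run_direction(xr, mr, compute_temporal_decay(mr),
                           np.ascontiguousarray(sprof[:, ::-1]), y, params, "bwd_")
    return cache["h"][0, ::-1], cache["xhat"][0, ::-1]


def bidirectional_impute(masked_trial: MaskedTrial, state, params: ModelParams) -> ImputationResult:
    """Impute one trial: averaged directional estimates at masked cells.

    If the model carries normalization statistics, values are z-scored on the
    way in and estimates un-scored on the way out. Observed cells of the
    completed series are the input values, bit-exact.
    """
    values = masked_trial.values
    m = masked_trial.mask
    if (m == 0).all():
        raise ValueError("trial is fully masked; nothing to condition on")
    if params.config.use_space and params.distances is None:
        raise ValueError("spatially gated model is missing its distance matrix")
    x = values
    if params.norm_mu is not None:
        x = (values - params.norm_mu) / params.norm_sd
    xv = np.nan_to_num(x, nan=0.0)[None]
    y = _state_array(state, 1, params.config)
    est = batch_estimates(xv, m[None], params, y)[0]
    if params.norm_mu is not None:
        est = est * params.norm_sd + params.norm_mu
    completed = np.where(m == 1, values, est)
    return ImputationResult(completed=completed, estimates=est, mask=m)


def impute_trial(params: ModelParams, masked_trial: MaskedTrial,
                 external_state=None) -> ImputationResult:
    """Convenience wrapper that encodes the trial's state before imputing."""
    cfg = params.config
    if not cfg.use_state:
        state = None
    elif cfg.state_encoder == "label":
        state = encode_state(masked_trial.label, params)
    elif cfg.state_encoder == "external":
        state = encode_state(external_state, params)
    else:
        x = masked_trial.values
        if params.norm_mu is not None:
            x = (x - params.norm_mu) / params.norm_sd
        state = encode_state(np.where(masked_trial.mask == 1, x, 0.0), params)
    return bidirectional_impute(masked_trial, state, params)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def montage_fingerprint(coords: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(np.round(coords, 12)).tobytes()).hexdigest()[:16]


def save_model(params: ModelParams, path) -> None:
    """Single-file artifact: weights, normalization, config echo, versioned header."""
    header = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(params.config),
        "montage_hash": params.montage_hash,
    }
    extras = {}
    if params.norm_mu is not None:
        extras["__norm_mu__"] = params.norm_mu
        extras["__norm_sd__"] = params.norm_sd
    if params.distances is not None:
        extras["__distances__"] = params.distances
    with open(path, "wb") as fh:  # file handle: keep the exact path, no suffixing
        np.savez(fh, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                 **params.arrays, **extras)


def load_model(path) -> ModelParams:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        if header["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {header['format_version']}")
        arrays = {k: npz[k] for k in npz.files if not k.startswith("__")}
        return ModelParams(
            config=ModelConfig(**header["config"]),
            arrays=arrays,
            norm_mu=npz["__norm_mu__"] if "__norm_mu__" in npz.files else None,
            norm_sd=npz["__norm_sd__"] if "__norm_sd__" in npz.files else None,
            distances=npz["__distances__"] if "__distances__" in npz.files else None,
            montage_hash=header["montage_hash"],
        )
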