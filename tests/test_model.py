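"""Model mechanics: gates, filling, recurrence against a hand oracle, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegimpute.masking import MaskedTrial
from eegimpute.model import (
    ModelConfig,
    ModelParams,
    StateVector,
    bidirectional_impute,
    combine_decay,
    directional_pass,
    encode_state,
    fill_input,
    init_params,
    load_model,
    loss_and_grads,
    mse_loss,
    save_model,
    spatial_decay_factor,
    temporal_decay_factor,
)
from eegimpute.montage import pairwise_distance

from .helpers import tiny_hand_params


def _scalar_params(w_beta, w_eta=0.0, b=0.0):
    cfg = ModelConfig(n_channels=1, hidden_size=1, use_state=False)
    return ModelParams(
        config=cfg,
        arrays={
            "W_beta": np.array([[w_beta]]), "b_beta": np.array([b]),
            "W_eta": np.array([[w_eta]]), "b_eta": np.array([b]),
        },
    )


class TestDecayGates:
    def test_zero_weights_give_unit_factor(self):
        p = _scalar_params(0.0, 0.0)
        assert temporal_decay_factor(np.array([5.0]), p) == pytest.approx(1.0)
        assert spatial_decay_factor(np.array([5.0]), p) == pytest.approx(1.0)

    def test_nonpositive_preactivation_clamps_to_unit(self):
        p = _scalar_params(-2.0, -1.0)
        assert temporal_decay_factor(np.array([3.0]), p) == pytest.approx(1.0)
        assert spatial_decay_factor(np.array([0.0]), p) == pytest.approx(1.0)

    def test_scalar_closed_forms(self):
        assert temporal_decay_factor(np.array([2.0]), _scalar_params(1.0)) == pytest.approx(
            np.exp(-2.0), abs=1e-12
        )
        assert spatial_decay_factor(np.array([4.0]), _scalar_params(0.0, 0.5)) == pytest.approx(
            np.exp(-2.0), abs=1e-12
        )

    def test_factors_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            H, D = rng.integers(1, 6, 2)
            p = ModelParams(
                config=ModelConfig(n_channels=int(D), hidden_size=int(H), use_state=False),
                arrays={
                    "W_beta": rng.standard_normal((H, D)) * 3,
                    "b_beta": rng.standard_normal(H) * 3,
                    "W_eta": rng.standard_normal((H, D)) * 3,
                    "b_eta": rng.standard_normal(H) * 3,
                },
            )
            gaps = rng.uniform(0, 50, D)
            for f in (temporal_decay_factor(gaps, p), spatial_decay_factor(gaps, p)):
                assert (f > 0).all() and (f <= 1).all()

    def test_beta_nonincreasing_in_gaps_for_nonnegative_weights(self):
        rng = np.random.default_rng(1)
        p = ModelParams(
            config=ModelConfig(n_channels=3, hidden_size=4, use_state=False),
            arrays={"W_beta": rng.uniform(0, 1, (4, 3)), "b_beta": rng.uniform(-1, 1, 4)},
        )
        grid = np.linspace(0, 10, 25)
        for d in range(3):
            gaps = np.zeros((25, 3))
            gaps[:, d] = grid
            beta = temporal_decay_factor(gaps, p)
            assert (np.diff(beta, axis=0) <= 1e-15).all()


class TestCombineAndFill:
    def test_combine_limits_and_example(self):
        b, e = np.array([0.5, 1.0]), np.array([0.25, 1.0])
        np.testing.assert_array_equal(combine_decay(b, e, 0.0), b)
        np.testing.assert_allclose(combine_decay(np.ones(2), np.ones(2), 1.0), 2.0)
        assert combine_decay(np.array([0.5]), np.array([0.25]), 0.8)[0] == pytest.approx(0.7)
        with pytest.raises(ValueError):
            combine_decay(b, e, 1.5)
        with pytest.raises(ValueError):
            combine_decay(b, np.ones(3), 0.5)

    def test_fill_input_cases(self):
        x = np.array([1.0, np.nan])
        np.testing.assert_array_equal(fill_input(x, [1, 0], [9.0, 7.0]), [1.0, 7.0])
        np.testing.assert_array_equal(fill_input([1.0, 2.0], [1, 1], [9.0, 9.0]), [1.0, 2.0])
        np.testing.assert_array_equal(fill_input(x, [0, 0], [9.0, 7.0]), [9.0, 7.0])
        with pytest.raises(ValueError, match="observed"):
            fill_input([np.nan, 1.0], [1, 1], [0.0, 0.0])
        with pytest.raises(ValueError, match="finite"):
            fill_input(x, [1, 0], [1.0, np.nan])


def test_mse_loss_cases():
    mask = np.array([[1.0, 0.0], [0.0, 1.0]])
    gt = np.array([[np.nan, 2.0], [5.0, np.nan]])
    est = np.array([[0.0, 3.0], [2.0, 0.0]])  # errors 1 and 3 at the masked cells
    assert mse_loss(None, est, mask, gt) == pytest.approx(5.0)
    assert mse_loss(None, est, np.ones_like(mask), None) == 0.0
    perfect = np.where(mask == 0, gt, est)  # estimates equal truth at masked cells
    assert mse_loss(None, perfect, mask, gt) == 0.0
    with pytest.raises(ValueError):
        mse_loss(None, est, mask, None)


class TestStateEncoding:
    def test_one_hot_identity_embedding(self):
        p = init_params(ModelConfig(n_channels=2, hidden_size=2, n_classes=3), seed=0)
        p.arrays["embed"] = np.eye(3)
        np.testing.assert_array_equal(encode_state(2, p).y, [0, 0, 1])
        with pytest.raises(ValueError, match="label"):
            encode_state(None, p)

    def test_external_passthrough_and_length_check(self):
        cfg = ModelConfig(n_channels=2, hidden_size=2, state_encoder="external", state_dim=3)
        p = init_params(cfg, seed=0)
        v = np.array([0.1, -0.2, 0.3])
        np.testing.assert_array_equal(encode_state(v, p).y, v)
        with pytest.raises(ValueError, match="length"):
            encode_state(np.ones(5), p)

    def test_conv_features_deterministic(self):
        cfg = ModelConfig(n_channels=3, hidden_size=4, state_encoder="conv", n_conv_bins=4)
        p = init_params(cfg, seed=1)
        trial = np.random.default_rng(0).standard_normal((16, 3))
        a, b = encode_state(trial, p), encode_state(trial, p)
        np.testing.assert_array_equal(a.y, b.y)
        assert a.y.shape == (cfg.state_dim,)


# ---------------------------------------------------------------------------
# Straight-line recurrence oracle (2 channels, 3 steps, H=2)
# ---------------------------------------------------------------------------

_X = np.array([[1.0, np.nan], [0.5, -0.2], [np.nan, 0.3]])


def _oracle_pass(A, dist, lam, x, use_space=True):
    """Independent step-by-step recurrence: one direction, plain arithmetic."""
    T, D = x.shape
    m = np.isfinite(x).astype(float)
    delta = np.zeros((T, D))
    for t in range(1, T):
        for d in range(D):
            delta[t, d] = 1.0 if m[t - 1, d] == 1 else 1.0 + delta[t - 1, d]
    h = np.zeros(2)
    hs, xhats = [], []
    for t in range(T):
        beta = np.exp(-np.maximum(A["W_beta"] @ delta[t] + A["b_beta"], 0.0))
        if use_space:
            missing = m[t] == 0
            prof = dist[missing].mean(axis=0) if missing.any() else np.zeros(D)
            eta = np.exp(-np.maximum(A["W_eta"] @ prof + A["b_eta"], 0.0))
            gamma = beta + lam * eta
        else:
            gamma = beta
        hd = h * gamma
        xhat = A["W_x"] @ hd + A["b_x"]
        xc = np.where(m[t] == 1, np.nan_to_num(x[t]), xhat)
        h = np.tanh(A["W_xh"] @ xc + A["W_hh"] @ hd + A["b_h"])
        hs.append(h.copy())
        xhats.append(xhat)
    return np.array(hs), np.array(xhats)


def _oracle_arrays(params, prefix):
    A = params.arrays
    out = {k: A[k] for k in ("W_beta", "b_beta") if k in A}
    out.update({k: A.get(k) for k in ("W_eta", "b_eta")})
    for k in ("W_xh", "W_hh", "b_h", "W_x", "b_x"):
        out[k] = A[prefix + k]
    return out


def test_tiny_network_matches_straight_line_oracle():
    params = tiny_hand_params()
    lam, dist = params.config.lambda_mix, params.distances
    mt = MaskedTrial.from_values(_X)

    h_f, xhat_f = directional_pass(mt, None, params, "forward")
    oh_f, ox_f = _oracle_pass(_oracle_arrays(params, "fwd_"), dist, lam, _X)
    np.testing.assert_allclose(h_f, oh_f, atol=1e-10)
    np.testing.assert_allclose(xhat_f, ox_f, atol=1e-10)

    h_b, xhat_b = directional_pass(mt, None, params, "backward")
    oh_b, ox_b = _oracle_pass(_oracle_arrays(params, "bwd_"), dist, lam, _X[::-1])
    np.testing.assert_allclose(h_b, oh_b[::-1], atol=1e-10)
    np.testing.assert_allclose(xhat_b, ox_b[::-1], atol=1e-10)

    result = bidirectional_impute(mt, None, params)
    np.testing.assert_allclose(result.estimates, 0.5 * (ox_f + ox_b[::-1]), atol=1e-10)
    np.testing.assert_allclose(
        result.completed, np.where(mt.mask == 1, _X, 0.5 * (ox_f + ox_b[::-1])), atol=1e-10
    )


def test_single_step_zero_weights_give_zero_estimate():
    params = tiny_hand_params()
    for k in params.arrays:
        params.arrays[k] = np.zeros_like(params.arrays[k])
    mt = MaskedTrial.from_values(np.array([[0.7, np.nan]]))
    _, xhat = directional_pass(mt, None, params, "forward")
    np.testing.assert_array_equal(xhat, [[0.0, 0.0]])


def test_backward_pass_equals_forward_on_reversed_trial():
    """Structural check: the backward direction is the forward recurrence on
    the time-reversed trial, read back in reverse, with its own weights."""
    params = tiny_hand_params()
    # give both directions identical weights so the equivalence is observable
    for k in ("W_xh", "W_hh", "b_h", "W_x", "b_x"):
        params.arrays["bwd_" + k] = params.arrays["fwd_" + k].copy()
    mt = MaskedTrial.from_values(_X)
    mt_rev = MaskedTrial.from_values(_X[::-1].copy())
    h_b, xhat_b = directional_pass(mt, None, params, "backward")
    h_f, xhat_f = directional_pass(mt_rev, None, params, "forward")
    np.testing.assert_allclose(h_b, h_f[::-1], atol=1e-12)
    np.testing.assert_allclose(xhat_b, xhat_f[::-1], atol=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_imputation_never_alters_observed_values(seed):
    rng = np.random.default_rng(seed)
    T, D = int(rng.integers(3, 12)), 4
    x = rng.standard_normal((T, D)) * 10
    x[rng.random((T, D)) < 0.3] = np.nan
    if not np.isfinite(x).any():
        x[0, 0] = 1.0
    cfg = ModelConfig(n_channels=D, hidden_size=5, use_state=False)
    params = init_params(cfg, seed=seed % 1000)
    params.distances = pairwise_distance(rng.standard_normal((D, 3)))
    mt = MaskedTrial.from_values(x)
    res = bidirectional_impute(mt, None, params)
    obs = mt.mask == 1
    assert np.array_equal(res.completed[obs], x[obs])  # bit-exact
    assert np.isfinite(res.completed).all()


def test_fully_masked_trial_rejected_but_masked_channel_allowed():
    cfg = ModelConfig(n_channels=2, hidden_size=3, use_state=False, use_space=False)
    params = init_params(cfg, seed=0)
    with pytest.raises(ValueError, match="fully masked"):
        bidirectional_impute(MaskedTrial.from_values(np.full((4, 2), np.nan)), None, params)
    x = np.array([[1.0, np.nan], [2.0, np.nan], [0.5, np.nan]])
    res = bidirectional_impute(MaskedTrial.from_values(x), None, params)
    assert np.isfinite(res.completed).all()


def test_gradients_match_finite_differences():
    rng = np.random.default_rng(4)
    B, T, D, H = 2, 4, 3, 3
    cfg = ModelConfig(n_channels=D, hidden_size=H, n_classes=2, state_encoder="label")
    params = init_params(cfg, seed=3)
    params.distances = pairwise_distance(rng.standard_normal((D, 3)) * 2)
    x = rng.standard_normal((B, T, D))
    m = (rng.random((B, T, D)) > 0.4).astype(float)
    score = (1.0 - m) * (rng.random((B, T, D)) > 0.3)
    score[0, 1, 0], m[0, 1, 0] = 1.0, 0.0  # guarantee a scored cell
    xv = x * (m > 0)
    labels = np.array([0, 1])

    def run(route):
        y = params.arrays["embed"][labels]
        return loss_and_grads(xv, m, x, score, params, y=y, y_backprop=route)

    _, grads = run(("embed", labels))
    eps = 1e-6
    for key, arr in params.arrays.items():
        it = np.nditer(arr, flags=["multi_index"])
        num = np.zeros_like(arr)
        for _ in it:
            i = it.multi_index
            old = arr[i]
            arr[i] = old + eps
            lp, _ = run(None)
            arr[i] = old - eps
            lm, _ = run(None)
            arr[i] = old
            num[i] = (lp - lm) / (2 * eps)
        np.testing.assert_allclose(grads[key], num, atol=1e-7, err_msg=key)


def test_model_serialization_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    cfg = ModelConfig(n_channels=3, hidden_size=4, n_classes=2)
    params = init_params(cfg, seed=8)
    params.distances = pairwise_distance(rng.standard_normal((3, 3)))
    params.norm_mu = np.array([0.0, 1.0, -1.0])
    params.norm_sd = np.array([1.0, 2.0, 0.5])
    path = tmp_path / "model.npz"
    save_model(params, path)
    loaded = load_model(path)
    assert loaded.config == cfg
    for k in params.arrays:
        np.testing.assert_array_equal(loaded.arrays[k], params.arrays[k])
    x = rng.standard_normal((6, 3))
    x[1, 2] = np.nan
    mt = MaskedTrial.from_values(x)
    state = StateVector(params.arrays["embed"][1])
    np.testing.assert_array_equal(
        bidirectional_impute(mt, state, params).estimates,
        bidirectional_impute(mt, state, loaded).estimates,
    )


def test_backbone_reduction_matches_ablated_model():
    """With the spatial gate removed and a zero-length state vector the model
    is exactly the mask + temporal-decay backbone: same parameters, same output."""
    cfg_ablated = ModelConfig(n_channels=3, hidden_size=4, use_space=False,
                              use_state=False, lambda_mix=0.0)
    cfg_backbone = ModelConfig(n_channels=3, hidden_size=4, use_space=False,
                               use_state=False, lambda_mix=0.0)
    a = init_params(cfg_ablated, seed=5)
    b = init_params(cfg_backbone, seed=5)
    assert sorted(a.arrays) == sorted(b.arrays)
    assert not any(k.startswith(("W_eta", "embed")) for k in a.arrays)
    assert a.n_parameters() == b.n_parameters()
    x = np.random.default_rng(0).standard_normal((5, 3))
    x[2, 1] = np.nan
    mt = MaskedTrial.from_values(x)
    np.testing.assert_array_equal(
        bidirectional_impute(mt, None, a).estimates,
        bidirectional_impute(mt, None, b).estimates,
    )
    # the spatially gated model at the same seed has strictly more parameters
    full = init_params(ModelConfig(n_channels=3, hidden_size=4, use_state=False), seed=5)
    assert full.n_parameters() > a.n_parameters()
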