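"""Test-only helpers: a minimal synthetic EDF+ writer and a tiny hand model."""

import numpy as np

from eegimpute.model import ModelConfig, ModelParams


def write_synthetic_edf(path, data_uv, sfreq, ch_names, event_times, event_label="stim"):
    """Write a minimal synthetic EDF+ file (int16, 1-second records, one
    annotation channel carrying the event markers). Test fixture only."""
    D, n = data_uv.shape
    spr = int(sfreq)
    n_rec = n // spr
    ann_spr = 32
    ns = D + 1
    pmin, pmax = -3276.8, 3276.7

    def pad(s, w):
        return s.encode("ascii")[:w].ljust(w)

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2020 X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8), pad("EDF+C", 44), pad(str(n_rec), 8),
        pad("1", 8), pad(str(ns), 4),
    ])
    labels = [pad(c, 16) for c in ch_names] + [pad("EDF Annotations", 16)]
    per_signal = [
        labels,
        [pad("", 80)] * ns,
        [pad("uV", 8)] * D + [pad("", 8)],
        [pad(str(pmin), 8)] * D + [pad("-1", 8)],
        [pad(str(pmax), 8)] * D + [pad("1", 8)],
        [pad("-32768", 8)] * ns,
        [pad("32767", 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(spr), 8)] * D + [pad(str(ann_spr), 8)],
        [pad("", 32)] * ns,
    ]
    out = [hdr, b"".join(b"".join(f) for f in per_signal)]
    dig = np.clip(np.round(data_uv / (pmax - pmin) * 65535), -32768, 32767).astype("<i2")
    for r in range(n_rec):
        for d in range(D):
            out.append(dig[d, r * spr : (r + 1) * spr].tobytes())
        tal = f"+{r}\x14\x14\x00".encode()
        for t in event_times:
            if r <= t < r + 1:
                tal += f"+{t:g}\x14{event_label}\x14\x00".encode()
        out.append(tal.ljust(2 * ann_spr, b"\x00"))
    with open(path, "wb") as fh:
        fh.write(b"".join(out))


def tiny_hand_params(lam=0.8, use_space=True):
    """2-channel, H=2 model with small fixed weights for straight-line oracles."""
    cfg = ModelConfig(
        n_channels=2, hidden_size=2, lambda_mix=lam,
        use_space=use_space, use_state=False,
    )
    arrays = {
        "W_beta": np.array([[0.10, 0.20], [0.30, 0.05]]),
        "b_beta": np.array([0.01, -0.02]),
        "fwd_W_xh": np.array([[0.20, -0.10], [0.05, 0.30]]),
        "fwd_W_hh": np.array([[0.10, 0.05], [-0.04, 0.20]]),
        "fwd_b_h": np.array([0.02, -0.01]),
        "fwd_W_x": np.array([[0.30, -0.20], [0.10, 0.40]]),
        "fwd_b_x": np.array([0.05, -0.03]),
        "bwd_W_xh": np.array([[-0.15, 0.25], [0.10, -0.05]]),
        "bwd_W_hh": np.array([[0.20, -0.10], [0.05, 0.15]]),
        "bwd_b_h": np.array([-0.02, 0.03]),
        "bwd_W_x": np.array([[0.25, 0.15], [-0.30, 0.20]]),
        "bwd_b_x": np.array([-0.01, 0.04]),
    }
    if use_space:
        arrays["W_eta"] = np.array([[0.40, 0.10], [0.05, 0.25]])
        arrays["b_eta"] = np.array([0.00, 0.02])
    params = ModelParams(config=cfg, arrays=arrays)
    params.distances = np.array([[0.0, 1.5], [1.5, 0.0]])
    return params
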