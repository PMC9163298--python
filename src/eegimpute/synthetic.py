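"""Synthetic ERP-like trial generator.

Emulates the structure the imputer exploits in evoked-response recordings:
each class carries a stereotyped deflection (a Gaussian-windowed half-sine) at
a class-specific latency, strongest at a class-specific focal electrode and
decaying over the scalp as ``exp(-distance/scale)``; background noise is a mix
of spatially correlated activity (covariance ``exp(-d_pq/scale)`` over the
montage, so nearby channels co-fluctuate) and white sensor noise, optionally
AR(1)-colored in time. Trial-to-trial amplitude and latency jitter give the
per-trial variability real evoked data shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import EEGTrialSet
from .montage import Montage, pairwise_distance

__all__ = ["SynthSpec", "generate_dataset", "class_average"]


@dataclass
class SynthSpec:
    """Generation parameters (amplitudes/noise in microvolts, times in samples)."""

    n_trials: int
    n_samples: int
    montage: Montage
    n_classes: int = 3
    peak_latency_per_class: tuple[int, ...] | None = None  # default: evenly spread
    peak_amplitude: float = 8.0
    spatial_kernel_scale: float = 0.8
    noise_sd: float = 2.0
    seed: int = 0
    bump_width: int | None = None  # default: n_samples // 10
    amplitude_jitter: float = 0.1  # relative sd of per-trial amplitude
    latency_jitter: int = 2  # sd in samples of per-trial latency shift
    spatial_noise_fraction: float = 0.5  # share of noise variance that is correlated
    ar_coeff: float = 0.0  # AR(1) temporal coloring of the noise (0 = white)
    sampling_rate: float = 128.0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if self.peak_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")
        if self.peak_latency_per_class is None:
            # Evenly spaced latencies, away from the trial edges.
            lats = np.linspace(0.2, 0.8, self.n_classes) * self.n_samples
            self.peak_latency_per_class = tuple(int(round(x)) for x in lats)
        if len(self.peak_latency_per_class) != self.n_classes:
            raise ValueError("need one peak latency per class")
        if not all(0 <= l < self.n_samples for l in self.peak_latency_per_class):
            raise ValueError("peak latencies must lie within [0, n_samples)")
        if self.bump_width is None:
            self.bump_width = max(self.n_samples // 10, 2)
        if self.n_samples < 2 * self.bump_width:
            raise ValueError("trial too short for the bump support")
        if not 0.0 <= self.spatial_noise_fraction <= 1.0:
            raise ValueError("spatial_noise_fraction must be in [0, 1]")


def _bump(t: np.ndarray, latency: float, width: int) -> np.ndarray:
    """Gaussian-windowed half-sine deflection peaking at `latency`."""
    rel = t - latency
    half_sine = np.where(np.abs(rel) <= width, np.cos(0.5 * np.pi * rel / width), 0.0)
    window = np.exp(-(rel**2) / (2.0 * (width / 1.5) ** 2))
    return half_sine * window


def generate_dataset(spec: SynthSpec) -> EEGTrialSet:
    """Draw ``n_trials`` labeled trials; deterministic given ``spec.seed``.

    Labels cycle through the classes so per-class counts differ by at most one.
    """
    if spec.montage.n_channels == 0:
        raise ValueError("montage is empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xE6]))
    D = spec.montage.n_channels
    T = spec.n_samples
    dist = pairwise_distance(spec.montage)

    focal = rng.choice(D, size=spec.n_classes, replace=spec.n_classes > D)
    with np.errstate(over="ignore"):
        profiles = np.exp(-dist[focal] / spec.spatial_kernel_scale)  # (K, D)

    # Spatially correlated noise factor: exp(-d/scale) kernel over electrodes.
    kernel = np.exp(-dist / spec.spatial_kernel_scale)
    chol = np.linalg.cholesky(kernel + 1e-9 * np.eye(D))

    t = np.arange(T, dtype=np.float64)
    labels = np.arange(spec.n_trials, dtype=np.int64) % spec.n_classes
    values = np.empty((spec.n_trials, T, D))
    for i in range(spec.n_trials):
        k = int(labels[i])
        amp = spec.peak_amplitude * max(1.0 + spec.amplitude_jitter * rng.standard_normal(), 0.0)
        lat = spec.peak_latency_per_class[k]
        if spec.latency_jitter:
            lat = float(np.clip(lat + rng.normal(0, spec.latency_jitter), 0, T - 1))
        signal = amp * np.outer(_bump(t, lat, spec.bump_width), profiles[k])

        white = rng.standard_normal((T, D))
        correlated = rng.standard_normal((T, D)) @ chol.T
        if spec.ar_coeff:
            a = spec.ar_coeff
            for arr in (white, correlated):
                for s in range(1, T):
                    arr[s] = a * arr[s - 1] + np.sqrt(1 - a**2) * arr[s]
        rho = spec.spatial_noise_fraction
        noise = spec.noise_sd * (np.sqrt(rho) * correlated + np.sqrt(1 - rho) * white)
        values[i] = signal + noise

    return EEGTrialSet(
        values=values,
        channel_names=list(spec.montage.channel_names),
        sampling_rate=spec.sampling_rate,
        labels=labels,
        provenance={
            "generator": "synthetic-erp",
            "seed": int(spec.seed),
            "n_classes": spec.n_classes,
            "focal_channels": [int(f) for f in focal],
        },
    )


def class_average(trials: EEGTrialSet, label: int) -> np.ndarray:
    """Pointwise mean over all trials carrying ``label`` (the evoked average)."""
    if trials.labels is None:
        raise ValueError("trial set has no labels")
    sel = trials.labels == label
    if not sel.any():
        raise ValueError(f"no trials with label {label}")
    return trials.values[sel].mean(axis=0)
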