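"""Observation masks and temporal decay for artifact-bearing trials.

A trial is a ``(T, D)`` matrix in microvolts with ``NaN`` marking artifact
samples. The binary mask flags observed cells; the temporal decay matrix
counts, per channel, how long ago the most recent observed sample occurred
(unit timestamp spacing), which downstream gates turn into a multiplicative
discount on stale hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskedTrial", "compute_mask", "compute_temporal_decay"]


def compute_mask(values: np.ndarray) -> np.ndarray:
    """Binary observation mask: 1 where ``values`` is finite, 0 at NaN cells."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("trial values must be a (T, D) matrix")
    if values.shape[0] == 0:
        raise ValueError("trial has a zero-length time axis")
    return np.isfinite(values).astype(np.float64)


def compute_temporal_decay(mask: np.ndarray, sampling_rate: float | None = None) -> np.ndarray:
    """Per-cell time since the last observed sample.

    Recursion per channel (unit spacing between timestamps)::

        delta[0] = 0
        delta[t] = 1               if mask[t-1] == 1
        delta[t] = 1 + delta[t-1]  if mask[t-1] == 0

    so a run of masked samples accumulates an ever-larger gap, resetting one
    step after any observed sample. Works on ``(T, D)`` or batched
    ``(..., T, D)`` masks. If ``sampling_rate`` is given, the result is scaled
    by ``1/sampling_rate`` (seconds instead of samples).
    """
    mask = np.asarray(mask, dtype=np.float64)
    if mask.ndim < 2:
        raise ValueError("mask must be at least (T, D)")
    if not np.isin(mask, (0.0, 1.0)).all():
        raise ValueError("mask entries must be binary")
    T = mask.shape[-2]
    delta = np.zeros_like(mask)
    for t in range(1, T):
        delta[..., t, :] = 1.0 + delta[..., t - 1, :] * (1.0 - mask[..., t - 1, :])
    if sampling_rate is not None:
        delta = delta / float(sampling_rate)
    return delta


@dataclass
class MaskedTrial:
    """A trial together with its derived mask and temporal decay.

    ``ground_truth``, when present, holds the original values at cells that
    were synthetically removed (finite exactly where ``mask == 0``); it is the
    scoring reference for self-supervised evaluation.
    """

    values: np.ndarray
    mask: np.ndarray
    temporal_decay: np.ndarray
    ground_truth: np.ndarray | None = None
    label: int | None = None
    sampling_rate: float = 128.0

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        ground_truth: np.ndarray | None = None,
        label: int | None = None,
        sampling_rate: float = 128.0,
    ) -> "MaskedTrial":
        values = np.asarray(values, dtype=np.float64)
        mask = compute_mask(values)
        trial = cls(
            values=values,
            mask=mask,
            temporal_decay=compute_temporal_decay(mask),
            ground_truth=ground_truth,
            label=label,
            sampling_rate=sampling_rate,
        )
        trial.validate()
        return trial

    def validate(self) -> None:
        if self.values.shape != self.mask.shape or self.values.shape != self.temporal_decay.shape:
            raise ValueError("values, mask and temporal_decay shapes must agree")
        if not ((self.mask == 1) == np.isfinite(self.values)).all():
            raise ValueError("mask must be 1 exactly at finite values")
        if self.ground_truth is not None:
            gt_finite = np.isfinite(self.ground_truth)
            if (gt_finite & (self.mask == 1)).any():
                raise ValueError("ground_truth must be defined only at masked cells")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_masked(self) -> int:
        return int((self.mask == 0).sum())
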