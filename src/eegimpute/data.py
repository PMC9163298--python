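"""In-memory containers for epoched multichannel EEG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGTrialSet:
    """A collection of equally shaped EEG trials.

    Parameters
    ----------
    values
        Array of shape ``(n_trials, T, D)`` in microvolts. ``NaN`` encodes
        artifact (missing) samples.
    channel_names
        ``D`` channel labels, in the column order of ``values``.
    sampling_rate
        Sampling frequency in Hz.
    labels
        Optional per-trial integer class labels, length ``n_trials``.
    ground_truth
        Optional ``(n_trials, T, D)`` array holding the original values at
        synthetically removed cells (``NaN`` elsewhere). Present only on sets
        produced by the corruption stage.
    provenance
        Free-form record of how the set was produced (seeds, generator spec).
    """

    values: np.ndarray
    channel_names: list[str]
    sampling_rate: float = 128.0
    labels: np.ndarray | None = None
    ground_truth: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_trials, T, D)")
        if self.values.shape[2] != len(self.channel_names):
            raise ValueError(
                f"{self.values.shape[2]} channels in values but "
                f"{len(self.channel_names)} channel names"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels length must match n_trials")
        if self.ground_truth is not None:
            self.ground_truth = np.asarray(self.ground_truth, dtype=np.float64)
            if self.ground_truth.shape != self.values.shape:
                raise ValueError("ground_truth shape must match values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def __len__(self) -> int:
        return self.n_trials

    def label_of(self, i: int) -> int | None:
        return None if self.labels is None else int(self.labels[i])

    def subset(self, idx) -> "EEGTrialSet":
        idx = np.asarray(idx)
        return EEGTrialSet(
            values=self.values[idx],
            channel_names=list(self.channel_names),
            sampling_rate=self.sampling_rate,
            labels=None if self.labels is None else self.labels[idx],
            ground_truth=None if self.ground_truth is None else self.ground_truth[idx],
            provenance=dict(self.provenance),
        )
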