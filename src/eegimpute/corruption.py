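"""Self-supervised artifact synthesis: remove observed values, keep the truth.

Corruption replaces a stated fraction of the *observed* cells of a trial with
NaN while retaining the removed values as ground truth, which makes imputation
quality measurable on any recording. Pointwise removal draws cells uniformly
without replacement; burst mode removes contiguous single-channel runs, closer
to how real motion/EMG artifacts occupy the record.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import EEGTrialSet
from .masking import MaskedTrial

__all__ = ["CorruptionSpec", "PAPER_RATES", "synthesize_artifacts", "corrupt_dataset", "rate_grid"]

#: The standard evaluation grid of synthesized-artifact rates.
PAPER_RATES = (0.025, 0.05, 0.075, 0.10, 0.125, 0.15, 0.175, 0.20)


@dataclass(frozen=True)
class CorruptionSpec:
    rate: float
    seed: int
    pattern: str = "pointwise"
    burst_length_range: tuple[int, int] = (5, 20)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"corruption rate must be in [0, 1], got {self.rate}")
        if self.pattern not in ("pointwise", "burst"):
            raise ValueError(f"unknown corruption pattern {self.pattern!r}")
        lo, hi = self.burst_length_range
        if not (0 < lo <= hi):
            raise ValueError("burst_length_range must be positive and ordered")


def _derive_seed(base_seed: int, *keys: int) -> int:
    """Deterministic, collision-resistant child seed below 2**31."""
    return int(np.random.SeedSequence([int(base_seed), *map(int, keys)]).generate_state(1)[0] % (2**31))


def synthesize_artifacts(
    trial: np.ndarray,
    spec: CorruptionSpec,
    label: int | None = None,
    sampling_rate: float = 128.0,
) -> MaskedTrial:
    """Remove ``floor(rate * n_observed)`` observed cells from one trial.

    Cells already NaN in the input are left untouched and never scored.
    Pointwise mode hits the target count exactly; burst mode adds whole
    single-channel runs until the target is reached (overshooting by at most
    one burst). Deterministic given ``spec.seed``.
    """
    values = np.asarray(trial, dtype=np.float64)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("trial must be a nonempty (T, D) matrix")
    observed = np.isfinite(values)
    rng = np.random.default_rng(spec.seed)
    target = int(np.floor(spec.rate * observed.sum()))

    removed = np.zeros_like(observed)
    if target > 0 and spec.pattern == "pointwise":
        flat_obs = np.flatnonzero(observed.ravel())
        chosen = rng.choice(flat_obs, size=target, replace=False)
        removed.ravel()[chosen] = True
    elif target > 0:
        T, D = values.shape
        lo, hi = spec.burst_length_range
        while removed.sum() < target:
            d = int(rng.integers(D))
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(max(T - length + 1, 1)))
            seg = slice(start, min(start + length, T))
            removed[seg, d] |= observed[seg, d]

    corrupted = values.copy()
    corrupted[removed] = np.nan
    ground_truth = np.full_like(values, np.nan)
    ground_truth[removed] = values[removed]
    return MaskedTrial.from_values(
        corrupted, ground_truth=ground_truth, label=label, sampling_rate=sampling_rate
    )


def corrupt_dataset(dataset: EEGTrialSet, spec: CorruptionSpec) -> EEGTrialSet:
    """Apply :func:`synthesize_artifacts` trial-wise with per-trial child seeds."""
    out = np.empty_like(dataset.values)
    gt = np.empty_like(dataset.values)
    for i in range(dataset.n_trials):
        mt = synthesize_artifacts(
            dataset.values[i],
            replace(spec, seed=_derive_seed(spec.seed, i)),
            sampling_rate=dataset.sampling_rate,
        )
        out[i] = mt.values
        gt[i] = mt.ground_truth
    prov = dict(dataset.provenance)
    prov["corruption"] = {"rate": spec.rate, "seed": spec.seed, "pattern": spec.pattern}
    return EEGTrialSet(
        values=out,
        channel_names=list(dataset.channel_names),
        sampling_rate=dataset.sampling_rate,
        labels=dataset.labels,
        ground_truth=gt,
        provenance=prov,
    )


def rate_grid(spec_base: CorruptionSpec, rates=PAPER_RATES) -> list[CorruptionSpec]:
    """One spec per rate, each with a child seed split from the base seed."""
    specs = []
    for j, rate in enumerate(rates):
        specs.append(replace(spec_base, rate=float(rate), seed=_derive_seed(spec_base.seed, 7, j)))
    return specs
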