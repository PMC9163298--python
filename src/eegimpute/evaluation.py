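"""Imputation metrics, the mean baseline, the rate sweep and ablation harness.

MAE and RMSE are computed only over masked cells, comparing imputed values
against the held-out ground truth — scoring observed cells would reward
copying the input. RMSE >= MAE always holds on the same cells (power-mean
inequality), which the report constructor asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corruption import CorruptionSpec, _derive_seed, synthesize_artifacts
from .data import EEGTrialSet
from .masking import MaskedTrial
from .model import ImputationResult, ModelParams, impute_trial
from .montage import Montage
from .training import TrainConfig, split_validation, train

__all__ = [
    "MetricReport",
    "mae",
    "rmse",
    "mean_impute",
    "MeanImputer",
    "TrainedImputer",
    "evaluate_imputer",
    "rate_sweep",
    "ablation_report",
    "ABLATION_ARMS",
]

ABLATION_ARMS = ("full", "no_state", "no_space", "no_state_space")


def mae(truth, predicted) -> float:
    """Mean absolute difference over scored positions."""
    truth, predicted = np.asarray(truth, float).ravel(), np.asarray(predicted, float).ravel()
    if truth.size == 0 or truth.size != predicted.size:
        raise ValueError("need equal-length, nonempty vectors")
    return float(np.mean(np.abs(truth - predicted)))


def rmse(truth, predicted) -> float:
    """Root mean squared difference over scored positions."""
    truth, predicted = np.asarray(truth, float).ravel(), np.asarray(predicted, float).ravel()
    if truth.size == 0 or truth.size != predicted.size:
        raise ValueError("need equal-length, nonempty vectors")
    return float(np.sqrt(np.mean((truth - predicted) ** 2)))


@dataclass
class MetricReport:
    mae: float
    rmse: float
    n_masked: int
    method: str
    rate: float | None = None
    seed: int | None = None
    per_channel: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_masked <= 0:
            raise ValueError("report needs at least one masked cell")
        if self.rmse < self.mae - 1e-12 or self.mae < 0:
            raise ValueError("metrics violate 0 <= MAE <= RMSE")


def mean_impute(masked_trial: MaskedTrial) -> ImputationResult:
    """Fill each masked cell with its channel's observed within-trial average.

    A fully masked channel falls back to the trial-global observed mean; a
    fully masked trial is an error.
    """
    values, mask = masked_trial.values, masked_trial.mask
    obs = mask == 1
    if not obs.any():
        raise ValueError("fully masked trial: no observed values to average")
    global_mean = values[obs].mean()
    n_obs = obs.sum(axis=0)
    sums = np.where(obs, values, 0.0).sum(axis=0)
    channel_mean = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), global_mean)
    estimates = np.tile(channel_mean, (values.shape[0], 1))
    return ImputationResult(
        completed=np.where(obs, values, estimates), estimates=estimates, mask=mask
    )


class MeanImputer:
    """Per-trial, per-channel mean-imputation baseline."""

    name = "mean"

    def impute(self, masked_trial: MaskedTrial) -> ImputationResult:
        return mean_impute(masked_trial)


class TrainedImputer:
    """Fitted model wrapper with the imputer interface used by the harnesses."""

    def __init__(self, params: ModelParams, name: str = "model"):
        self.params = params
        self.name = name

    def impute(self, masked_trial: MaskedTrial) -> ImputationResult:
        return impute_trial(self.params, masked_trial)


def _score_trials(imputer, trials: list[MaskedTrial], method: str,
                  rate=None, seed=None) -> MetricReport:
    """Pool masked-cell errors over trials into one report."""
    truths, preds, chans = [], [], []
    for mt in trials:
        res = imputer.impute(mt)
        scored = (mt.mask == 0) & np.isfinite(mt.ground_truth)
        truths.append(mt.ground_truth[scored])
        preds.append(res.estimates[scored])
        chans.append(np.nonzero(scored)[1])
    g = np.concatenate(truths)
    p = np.concatenate(preds)
    ch = np.concatenate(chans)
    per_channel = {
        int(d): {"mae": mae(g[ch == d], p[ch == d]), "n": int((ch == d).sum())}
        for d in np.unique(ch)
    }
    return MetricReport(
        mae=mae(g, p), rmse=rmse(g, p), n_masked=int(g.size),
        method=method, rate=rate, seed=seed, per_channel=per_channel,
    )


def evaluate_imputer(imputer, dataset: EEGTrialSet, spec: CorruptionSpec) -> MetricReport:
    """Corrupt a clean dataset per `spec`, impute, score on the removed cells."""
    if spec.rate <= 0:
        raise ValueError("corruption rate must be positive to score anything")
    trials = [
        synthesize_artifacts(
            dataset.values[i], replace(spec, seed=_derive_seed(spec.seed, i)),
            label=dataset.label_of(i), sampling_rate=dataset.sampling_rate,
        )
        for i in range(dataset.n_trials)
    ]
    return _score_trials(imputer, trials, getattr(imputer, "name", "unknown"),
                         rate=spec.rate, seed=spec.seed)


def rate_sweep(model_or_baseline, dataset: EEGTrialSet, rates, seeds) -> list[MetricReport]:
    """One report per (rate, seed): corrupt, impute, score. Sorted by rate."""
    if len(list(seeds)) == 0:
        raise ValueError("need at least one seed")
    reports = []
    for rate in sorted(rates):
        for seed in seeds:
            reports.append(
                evaluate_imputer(
                    model_or_baseline, dataset, CorruptionSpec(rate=rate, seed=int(seed))
                )
            )
    return reports


def ablation_report(
    dataset: EEGTrialSet,
    montage: Montage,
    base_config: TrainConfig,
    eval_rate: float = 0.10,
    eval_fraction: float = 0.2,
) -> dict[str, MetricReport]:
    """Train and score the four structural arms under identical seeds/corruption.

    The dataset is split once into fit/evaluation parts; every arm trains on
    the same fit trials and is scored on the same corrupted evaluation trials.
    """
    fit_set, eval_set = split_validation(dataset, eval_fraction, base_config.seed)
    spec = CorruptionSpec(rate=eval_rate, seed=_derive_seed(base_config.seed, 0xE))
    out: dict[str, MetricReport] = {}
    for arm in ABLATION_ARMS:
        params, _ = train(fit_set, montage, replace(base_config, ablation=arm))
        report = evaluate_imputer(TrainedImputer(params, name=arm), eval_set, spec)
        out[arm] = report
    return out
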