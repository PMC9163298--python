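"""Shared fixtures: montages, synthetic benchmark datasets, a fitted model.

The expensive session fixtures define the standard synthetic benchmark used
by the end-to-end tests: a 32-channel, 200-trial, 128-sample, 3-class evoked
dataset (generator defaults), split 160/40 into fit and evaluation trials,
and one model trained to convergence on the fit part.
"""

import numpy as np
import pytest

from eegimpute import (
    SynthSpec,
    TrainConfig,
    generate_dataset,
    montage_22,
    montage_32,
    train,
)


@pytest.fixture(scope="session")
def m32():
    return montage_32()


@pytest.fixture(scope="session")
def m22():
    return montage_22()


@pytest.fixture(scope="session")
def erp_dataset(m32):
    """Standard benchmark: 200 trials, T=128, 3 classes, generator defaults."""
    return generate_dataset(
        SynthSpec(n_trials=200, n_samples=128, montage=m32, n_classes=3, seed=11)
    )


@pytest.fixture(scope="session")
def erp_split(erp_dataset):
    return erp_dataset.subset(np.arange(160)), erp_dataset.subset(np.arange(160, 200))


@pytest.fixture(scope="session")
def trained_model(erp_split, m32):
    """Full model fitted on the benchmark's 160 fit trials (H=32)."""
    fit_set, _ = erp_split
    params, history = train(
        fit_set, m32, TrainConfig(seed=5, hidden_size=32, max_epochs=60, patience=8)
    )
    return params, history


@pytest.fixture(scope="session")
def strong_state_dataset(m22):
    """State-structured fixture: large, spatially broad class-specific bumps."""
    return generate_dataset(
        SynthSpec(
            n_trials=150, n_samples=96, montage=m22, n_classes=3,
            peak_amplitude=20.0, noise_sd=1.5, spatial_kernel_scale=1.5, seed=21,
        )
    )
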