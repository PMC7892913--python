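"""Shared fixtures: small synthetic datasets and trained models.

Session-scoped fixtures keep the expensive pieces (training at realistic
channel counts) to a single run per session.
"""

import numpy as np
import pytest

from megfix.models import ModelConfig, build_model, train
from megfix.preprocessing import EpochSet, preprocess
from megfix.synthetic import SimulationConfig, simulate_epochs


def subset(epochs: EpochSet, idx) -> EpochSet:
    return EpochSet(
        epochs.data[idx], epochs.fs, epochs.window, np.asarray(epochs.labels)[idx], epochs.channel_ids
    )


def epochs_from(ds) -> EpochSet:
    return EpochSet(
        ds.epochs, ds.config.fs, ds.config.epoch_window, ds.labels, ds.layout.channel_ids
    )


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config: few channels and trials, short epoch."""
    return SimulationConfig(
        n_voluntary=60, n_spontaneous=60, n_channels=32, k_true=5,
        epoch_window=(-0.2, 0.5), seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_epochs(small_config)


@pytest.fixture(scope="session")
def small_prep(small_dataset):
    """Preprocessed small dataset: 32 channels x 87 timepoints at 125 Hz."""
    return preprocess(epochs_from(small_dataset), (-0.2, 0.5))


@pytest.fixture(scope="session")
def trained_small_lf(small_prep):
    """An LF model trained on the small planted-effect dataset."""
    cfg = ModelConfig(k=8, max_iterations=150, batch_size=48, seed=5)
    rng = np.random.default_rng(0)
    idx = rng.permutation(small_prep.n_trials)
    tr, va = idx[:90], idx[90:]
    model = build_model("LF", small_prep.n_channels, small_prep.n_times, cfg)
    train(model, subset(small_prep, tr), subset(small_prep, va), cfg)
    return model, subset(small_prep, tr)
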