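"""Shared fixtures: synthetic two-domain datasets and a reduced-size trained
model ("smoke run") reused by training, uncertainty and end-to-end tests.

The smoke protocol — 16^3 volumes, 4 classes x 10 per domain, width-reduced
networks, 200 generator steps — is the package's reference CPU experiment;
its constants live here so every test exercises the same conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from tomocycle.models import build_model
from tomocycle.simulate import SimulationParams, generate_fixture_datasets
from tomocycle.training import TrainingConfig, train

SMOKE_SIZE = 16
SMOKE_N_PER_CLASS = 10
SMOKE_MODEL = dict(base_width=4, n_res_blocks=2, critic_width=8)
SMOKE_STEPS = 200
SMOKE_SEED = 7


def smoke_config(**overrides) -> TrainingConfig:
    base = dict(
        lambda_cyc=10.0, lr=5e-4, clip_value=0.01, n_critic=2, batch_size=4,
        epochs=1000, adv_mode="wasserstein", input_noise_std=0.2,
        seed=SMOKE_SEED, max_steps=SMOKE_STEPS,
    )
    base.update(overrides)
    return TrainingConfig(**base)


@pytest.fixture(scope="session")
def fixture_domains():
    """Clean density maps (D) and degraded subtomograms (S), 4 classes x 10."""
    return generate_fixture_datasets(
        n_per_class=SMOKE_N_PER_CLASS, size=SMOKE_SIZE,
        params=SimulationParams(), seed=11,
    )


@pytest.fixture(scope="session")
def small_model():
    return build_model(SMOKE_SIZE, seed=1, **SMOKE_MODEL)


@pytest.fixture(scope="session")
def smoke_run(fixture_domains):
    """One 200-step Wasserstein training run on the fixture domains."""
    data_d, data_s = fixture_domains
    model = build_model(SMOKE_SIZE, seed=1, **SMOKE_MODEL)
    model, history = train(model, data_d, data_s, smoke_config())
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
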