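"""Shared fixtures.

The expensive artifacts (trained forecasters, the scaled control
experiments) are session-scoped so the acceptance-style tests and the
invariant checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ddfmpc.experiments import (
    ExperimentConfig,
    run_heterogeneous,
    run_homogeneous,
    train_pipeline,
)


@pytest.fixture(scope="session")
def study_cfg() -> ExperimentConfig:
    """Scaled study conditions: 10 trials x 500 ms, SNR-5 noise, 5 s training."""
    return ExperimentConfig(n_trials=10, duration=500.0,
                            train_duration=5000.0, seed=12345)


@pytest.fixture(scope="session")
def models(study_cfg):
    """One trained forecaster per neuron type, at the pipeline's default embedding
    (D_e = 2, delay 1; the data-driven selection of D_e is tested
    separately)."""
    return train_pipeline(study_cfg, select_dim=False)


@pytest.fixture(scope="session")
def homogeneous_results(study_cfg, models):
    return run_homogeneous(study_cfg, models)


@pytest.fixture(scope="session")
def heterogeneous_results(study_cfg, models):
    return run_heterogeneous(study_cfg, models)


@pytest.fixture(scope="session")
def type_i_training():
    """A noiseless 5 s Type-I recording at the control rate (10 kHz)."""
    from ddfmpc.neuron_sim import (
        NeuronParams, make_lorenz_current, simulate_cs,
    )

    lor = make_lorenz_current(tau=20.0, amplitude=1.8, duration=5000.0,
                              dt=0.02, x0=2.0, y0=3.0, z0=14.0)
    v, _ = simulate_cs(NeuronParams.type_i(), lor, None, duration=5000.0)
    return v.downsample(5), lor.downsample(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
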