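"""Shared fixtures: small synthetic datasets and the end-to-end fixture.

Everything is generated programmatically and seeded; the end-to-end
fixture configuration (6 channels, 40 trials per class, disjoint bands,
0.5 µV background vs 5 µV signal, reduced CWD grid and DBN epochs) is
chosen once for desk-scale runtimes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurotask.dbn import TrainConfig
from neurotask.pipeline import DetectorConfig, ExperimentConfig, FeatureConfig
from neurotask.qtfd import CWKernelParams
from neurotask.signal_io import Recording
from neurotask.synthetic import (
    GeneratorConfig,
    default_class_specs,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def separable_config(seed: int, n_channels: int = 6,
                     n_trials_per_class: int = 40) -> GeneratorConfig:
    """The separable 5-class world: disjoint bands, low background noise."""
    return GeneratorConfig(
        class_specs=default_class_specs(n_channels, 256.0),
        n_trials_per_class=n_trials_per_class,
        n_channels=n_channels,
        noise_amplitude=0.5,
        seed=seed,
    )


def fast_experiment_config(seed: int) -> ExperimentConfig:
    """Reduced-cost experiment settings (coarser CWD grid, 60 DBN epochs)."""
    return ExperimentConfig(
        features=FeatureConfig(
            kernel=CWKernelParams(alpha_kernel=1.0, window_len=63, n_fbins=128),
            win_len=1.0, hop=1.5,
        ),
        dbn=TrainConfig(epochs=60, batch_size=32),
        detector=DetectorConfig(kind="if"),
        seed=seed,
    )


@pytest.fixture(scope="session")
def separable_trialset():
    """One 200-trial separable dataset shared across tests."""
    return generate_dataset(separable_config(seed=7))


@pytest.fixture(scope="session")
def separable_features(separable_trialset):
    """Raw CWD feature matrix of the separable dataset (label-free)."""
    from neurotask.qtfd import trial_feature_matrix

    fc = fast_experiment_config(seed=0).features
    return trial_feature_matrix(separable_trialset, fc.kernel, fc.win_len,
                                fc.hop, fc.band_edges, fc.n_time_bins)


@pytest.fixture(scope="session")
def small_trialset():
    """Tiny 5-class set (8 trials/class, 4 s trials) for cheap pipeline tests."""
    cfg = GeneratorConfig(
        class_specs=default_class_specs(4, 128.0),
        n_trials_per_class=8,
        fs=128.0,
        trial_len=4.0,
        cue_time=1.0,
        n_channels=4,
        noise_amplitude=0.5,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture
def noise_recording(rng):
    """60 s of 4-channel Gaussian background at 10 µV RMS."""
    data = 10.0 * rng.standard_normal((60 * 256, 4))
    return Recording(data, 256.0, [f"ch{i}" for i in range(4)])
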