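import dataclasses

import pytest

from racquetclust.synth import default_synth_config, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 9 classes x 5 reps at the default noise level."""
    return generate_dataset(default_synth_config(seed=0, n_subjects=2, reps_per_test=5))


@pytest.fixture(scope="session")
def quiet_dataset():
    """Noise-free variant of the small protocol (separability checks)."""
    cfg = default_synth_config(seed=0, n_subjects=2, reps_per_test=5)
    quiet = dataclasses.replace(
        cfg,
        classes=tuple(
            dataclasses.replace(c, noise_sigma_accel=0.0, noise_sigma_gyro=0.0) for c in cfg.classes
        ),
    )
    return generate_dataset(quiet)


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    from racquetclust.model import HybridClusteringModel

    return HybridClusteringModel(small_dataset).fit(seed=0)


@pytest.fixture(scope="session")
def protocol_dataset():
    """The full collection protocol: 5 subjects x 9 classes x 20 reps."""
    return generate_dataset(default_synth_config(seed=0))


@pytest.fixture(scope="session")
def protocol_cv(protocol_dataset):
    """Fivefold stratified cross-validation at protocol scale, seed 0."""
    from racquetclust.evaluate import crossval

    return crossval(protocol_dataset, folds=5, seed=0)
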