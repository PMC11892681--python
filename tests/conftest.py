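import warnings

import numpy as np
import pytest

from msipd.synthetic import StudyConfig, generate_study_in_memory

warnings.filterwarnings("ignore", message=".*zero vehicle mean.*")


@pytest.fixture(scope="session")
def tiny_study():
    """Two small experiments, one tissue per arm, default noise."""
    cfg = StudyConfig(
        n_experiments=2,
        tissues_per_arm=1,
        grid_shape=(12, 12),
        seed=7,
        batch_log2_scale=(0.0, 0.5),
    )
    return generate_study_in_memory(cfg, imc=False)


@pytest.fixture(scope="session")
def zero_noise_study():
    """Noise- and jitter-free study for exact-closure checks."""
    cfg = StudyConfig(
        n_experiments=2,
        tissues_per_arm=1,
        grid_shape=(12, 12),
        seed=7,
        noise_cv=0.0,
        mz_jitter_ppm=0.0,
        batch_log2_scale=(0.0, 0.5),
    )
    return generate_study_in_memory(cfg, imc=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
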