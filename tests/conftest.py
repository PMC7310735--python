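import numpy as np
import pytest

from anxio.session import Baseline, compute_baseline
from anxio.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def strong_subject():
    """One subject with strong arousal effects (defaults) and no rating noise."""
    cfg = SimulationConfig(n_subjects=1, seed=11, rating_noise=0.0)
    [(subject, truth)] = generate_cohort(cfg)
    return subject, truth


@pytest.fixture(scope="session")
def strong_subject_baseline(strong_subject):
    subject, _ = strong_subject
    return compute_baseline(subject, "full_5min")


@pytest.fixture(scope="session")
def small_cohort():
    """Four strong-effect subjects with heterogeneous clip assignments."""
    cfg = SimulationConfig(n_subjects=4, seed=21)
    return generate_cohort(cfg)


@pytest.fixture
def flat_baseline():
    return Baseline(subject_id="flat", hr_rest_mean=60.0, eda_rest_min=2.0,
                    eda_rest_max=4.0, rest_window=(0.0, 300.0), br_rest_mean=12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
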