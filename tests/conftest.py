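import numpy as np
import pytest

from vmadapt.kinematics import extract_metrics
from vmadapt.learner import LearnerParams
from vmadapt.preprocess import preprocess_trials
from vmadapt.simulate import generate_cohort


@pytest.fixture(scope="session")
def clean_exp1():
    """Noise-free exp1 cohort (no motor noise, jumps, glitches or frame
    jitter) pushed through preprocessing and metric extraction."""
    cohort = generate_cohort(
        "exp1",
        n_per_group=2,
        params=LearnerParams().noiseless(),
        seed=11,
        frame_jitter=0.0,
        frame_rates=(60.0,),
    )
    clean, exclusions = preprocess_trials(cohort.trajectories)
    metrics = extract_metrics(clean, cohort.trials, exclusions)
    return cohort, metrics


@pytest.fixture(scope="session")
def noisy_exp1():
    """Default-parameter exp1 cohort with trajectories, preprocessed."""
    cohort = generate_cohort("exp1", n_per_group=2, seed=7)
    clean, exclusions = preprocess_trials(cohort.trajectories)
    metrics = extract_metrics(clean, cohort.trials, exclusions)
    return cohort, metrics


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
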