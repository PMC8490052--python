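import numpy as np
import pandas as pd
import pytest

from mipower import FEATURE_NAMES, FeatureMatrix, SyntheticConfig, extract_matrix, generate_trialset
from mipower.report import preprocess_trialset


def make_feature_matrix(seed: int, n_trials_per_class: int = 80, **kwargs) -> FeatureMatrix:
    """Generate one synthetic subject and run it through the full front end."""
    cfg = SyntheticConfig(seed=seed, n_trials_per_class=n_trials_per_class, **kwargs)
    trials = generate_trialset(cfg)
    return extract_matrix(preprocess_trialset(trials))


def informative_matrix(seed: int, n: int = 400, informative=(2, 5, 9), shift: float = 1.0):
    """A labeled feature table with known ground truth: the given canonical
    indices carry a class mean shift of ``shift`` standard deviations, the
    rest are pure noise."""
    rng = np.random.default_rng(seed)
    half = n // 2
    labels = np.array(["hand"] * half + ["feet"] * (n - half))
    values = rng.standard_normal((n, len(FEATURE_NAMES)))
    for idx in informative:
        values[half:, idx - 1] += shift
    order = rng.permutation(n)
    features = pd.DataFrame(values[order], columns=list(FEATURE_NAMES))
    return FeatureMatrix(features=features, labels=labels[order])


@pytest.fixture(scope="session")
def study_matrices():
    """Feature matrices for ten independent synthetic subjects (seeds 0-9)
    under the default class effect (alpha x1.4, beta x0.7 for feet)."""
    return {seed: make_feature_matrix(seed) for seed in range(10)}


@pytest.fixture(scope="session")
def null_matrices():
    """Subjects with no class effect at all: labels carry no information."""
    return {
        seed: make_feature_matrix(seed, class_effect={})
        for seed in (100, 101, 102)
    }


@pytest.fixture(scope="session")
def one_matrix(study_matrices):
    return study_matrices[0]
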