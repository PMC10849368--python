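import numpy as np
import pytest

from epibalance import AlleleFreqs, FitnessMatrix, RateParams


@pytest.fixture
def neutral():
    return FitnessMatrix.neutral()


@pytest.fixture
def no_rates():
    return RateParams(0.0, 0.0, 0.0)


def project_to_simplex(p: np.ndarray) -> np.ndarray:
    """Clip to nonnegative and renormalize; helper for perturbation tests."""
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def perturbed(freqs: AlleleFreqs, delta: np.ndarray) -> AlleleFreqs:
    return AlleleFreqs.from_array(project_to_simplex(freqs.as_array() + delta))
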