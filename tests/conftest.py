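import numpy as np
import pytest

from phaseone import study
from phaseone.crm import BmaCrmModel, QuadratureSpec, Skeleton, ToxicityTally


@pytest.fixture(scope="session")
def model() -> BmaCrmModel:
    """The study's default BMA-CRM design."""
    return study.default_model()


@pytest.fixture(scope="session")
def fast_model(model) -> BmaCrmModel:
    """Coarser quadrature for randomized property sweeps."""
    return model.replace(quadrature=QuadratureSpec(nodes=1025))


@pytest.fixture(scope="session")
def single_skeleton_model(model) -> BmaCrmModel:
    return model.replace(skeletons=(Skeleton((0.05, 0.10, 0.20)),),
                         prior_model_probs=(1.0,))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def random_tally(rng: np.random.Generator, n_doses: int = 3, max_n: int = 6) -> ToxicityTally:
    n = rng.integers(0, max_n + 1, size=n_doses)
    y = np.array([rng.integers(0, nj + 1) for nj in n])
    return ToxicityTally(n, y)
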