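import numpy as np
import pytest
from hypothesis import settings

from tapredict import TargetingModel, load_fixture_dataset
from tapredict.synthesis import ClassSpec, synth_feature_dataset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_entries():
    return load_fixture_dataset()


def separated_specs(spread: float = 0.15, n: int = 10):
    """Three classes whose inter-mean distance dwarfs the within-class spread."""
    return (
        ClassSpec("PO", 6.03, spread, 1.7, spread, n),
        ClassSpec("MITO", 1.12, spread, 1.2, spread, n),
        ClassSpec("ER", 0.21, spread, 2.8, spread, n),
    )


@pytest.fixture(scope="session")
def separable_blobs():
    """Well-separated synthetic 3-class feature data (seed 1)."""
    return synth_feature_dataset(separated_specs(), seed=1)


@pytest.fixture(scope="session")
def separable_model(separable_blobs):
    return TargetingModel.from_dataframe(separable_blobs, seed=0)


@pytest.fixture(scope="session")
def separable_results(separable_model):
    return separable_model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
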