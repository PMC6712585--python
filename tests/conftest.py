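import numpy as np
import pytest

from msca.clustering import adjusted_rand_index
from msca.pipeline import MSCA
from msca.simulate import SyntheticSpec, generate_multiview


@pytest.fixture(scope="session")
def default_dataset():
    """One clean draw of the default two-view, three-cluster benchmark."""
    return generate_multiview(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def fitted_default(default_dataset):
    """The full pipeline fitted once on the default benchmark."""
    model = MSCA(n_clusters=3, random_state=0).fit(default_dataset.views)
    return model


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced benchmark (30 samples, small feature counts) for fast tests."""
    spec = SyntheticSpec(
        n_per_cluster=15,
        n_features=(80, 60),
        seed=7,
    )
    return generate_multiview(spec)


def ari(a, b) -> float:
    return adjusted_rand_index(a, b)
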