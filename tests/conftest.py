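import numpy as np
import pytest

from brainseg import phantom, preprocess


@pytest.fixture(scope="session")
def default_case():
    """One deterministic phantom case at the desk-scale default shape."""
    return phantom.generate_phantom(phantom.PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_pairs():
    """Four preprocessed 64×64 slice/label pairs from jittered phantoms."""
    cases = phantom.generate_dataset(4, seed=7)
    return [preprocess.preprocess_case(vols, labels, target=64)
            for vols, labels in cases]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
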