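import pytest

from excompose import load_bundled_benchmark
from excompose.synthetic import make_chain_structure


@pytest.fixture(scope="session")
def benchmark():
    return load_bundled_benchmark()


@pytest.fixture()
def chain():
    return make_chain_structure(seed=3)
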