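import numpy as np
import pytest

from phenoscreen.demo import make_demo_dataset
from phenoscreen.pipeline import run_mining


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """Seeded demo dataset: (config, truth)."""
    outdir = tmp_path_factory.mktemp("demo")
    return make_demo_dataset(outdir, seed=11)


@pytest.fixture(scope="session")
def demo_mining(demo):
    """Demo dataset with the mining chain already run."""
    config, truth = demo
    outputs = run_mining(config)
    return config, truth, outputs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
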