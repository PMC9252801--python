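import numpy as np
import pytest

from protloc import synthetic
from protloc.benchmark import run_desk_experiment


@pytest.fixture(scope="session")
def desk_result():
    """Full desk-scale synthetic-recovery experiment (trains the model once
    per session; the expensive fixture behind the recovery assertions)."""
    return run_desk_experiment(seed=1, n=2000)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small fixed corpus with signal annotations, for fast model tests."""
    cfg = synthetic.desk_config(n=120)
    return cfg, synthetic.generate(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
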