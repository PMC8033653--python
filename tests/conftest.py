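import numpy as np
import pytest

from sanmf import pipeline, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient paper-like cohort shared by fast integration tests."""
    spec = synthetic.make_paperlike_spec(60, seed=7)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_run(small_cohort):
    """Core pipeline (prep + mine + factorize) on the small cohort."""
    return pipeline.run_in_memory(small_cohort, n_consensus_runs=4, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
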