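import numpy as np
import pytest

from staygreen import pipeline, synth
from staygreen.types import CausalSpec, SenescenceParams, TrialDesign


@pytest.fixture(scope="session")
def causal():
    return CausalSpec.default()


@pytest.fixture(scope="session")
def small_geno(causal):
    """221-cultivar, 800-marker structured panel with the default causal loci."""
    return synth.simulate_genotypes(221, 800, causal, seed=11)


@pytest.fixture(scope="session")
def small_trial(causal, small_geno):
    return synth.simulate_trial(TrialDesign(), small_geno, causal,
                                SenescenceParams(), seed=11)


@pytest.fixture(scope="session")
def demo():
    """Full default-scale pipeline run reused by the acceptance checks."""
    return pipeline.run_pipeline({"seed": 7, "n_markers": 2000})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
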