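import numpy as np
import pytest

from idpdissect import synthetic
from idpdissect.pipeline import RunConfig, run_benchmark


@pytest.fixture(scope="session")
def two_state_spec():
    templates = synthetic.generate_state_templates(2, 15, seed=1)
    return synthetic.GroundTruthEnsembleSpec(
        n_states=2, n_residues=15, templates=templates, jitter_sigma=0.05,
        transition_matrix=np.array([[0.95, 0.05], [0.05, 0.95]]), seed=7)


@pytest.fixture(scope="session")
def two_state_ensemble(two_state_spec):
    return synthetic.simulate_markov_ensemble(two_state_spec, 1000)


@pytest.fixture(scope="session")
def benchmark_report():
    """Full K=3 vs K=6 synthetic benchmark at the study conditions
    (1e5 frames per condition, 10 trajectories, fixed seed).  Session-scoped
    because it is the expensive end-to-end computation shared by the
    acceptance checks."""
    return run_benchmark(RunConfig(seed=1))
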