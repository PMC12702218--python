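import numpy as np
import pandas as pd
import pytest

from harmolib.model import IsolationScheme, PipelineConfig
from harmolib.synthetic import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def wide_scheme() -> IsolationScheme:
    return IsolationScheme(400.0, 1000.0, 16.0, staggered=True)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A fast three-matrix experiment still large enough for the 1% FDR
    filter to accept peptides (the +1 estimator needs > 100 accepted)."""
    return SimulationConfig(
        n_true_peptides=150,
        n_false_targets=60,
        n_decoys=210,
        n_interference_pairs=8,
        runs_per_matrix=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_sim_config):
    return simulate_experiment(small_sim_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_meta(run_ids, matrix_ids, groups=None, subjects=None) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "run_id": run_ids,
            "matrix_id": matrix_ids,
            "group": groups if groups is not None else [""] * len(run_ids),
        }
    )
    if subjects is not None:
        meta["subject"] = subjects
    return meta.set_index("run_id")
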