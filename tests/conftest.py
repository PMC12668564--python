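import numpy as np
import pytest

from d3impute.containers import ExpressionMatrix
from d3impute.pipeline import RunConfig, run_pipeline
from d3impute.synthdata import SimParams, apply_dropout_mask, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 20x12 random sparse count matrix."""
    values = rng.poisson(1.2, size=(20, 12)).astype(float)
    values[0] = 0  # keep one all-zero row around
    return ExpressionMatrix(
        values,
        [f"c{i}" for i in range(20)],
        [f"g{j}" for j in range(12)],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 3-group 150x400 simulation with 40% of non-zeros masked."""
    sp = SimParams(n_cells=150, n_genes=400, seed=7)
    X, groups = simulate_counts(sp)
    return apply_dropout_mask(X, 0.4, seed=44)


@pytest.fixture(scope="session")
def pipeline_cfg():
    def make(seed=1, **overrides):
        d = {
            "qc": {"min_genes": 1, "max_features": 10**6, "n_hvgs": 400},
            "transform": {"method": "log10"},
            "disc": {"beta": 0.01, "lambda_c": 0.01, "lambda_g": 0.01,
                     "k": 10, "p": 10, "max_iter": 200},
            "seed": seed,
            "evaluate": False,
        }
        for key, val in overrides.items():
            d.setdefault(key, {}).update(val) if isinstance(val, dict) else d.__setitem__(key, val)
        return RunConfig.from_dict(d)
    return make


@pytest.fixture(scope="session")
def pipeline_result(small_sim, pipeline_cfg):
    """One pipeline run on the masked simulation, shared across tests."""
    return run_pipeline(pipeline_cfg(), sc=small_sim.masked, write=False)
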