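import numpy as np
import pytest

from allsub import ExpressionMatrix, SyntheticConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study used by pipeline-level tests (kept small for speed)."""
    cfg = SyntheticConfig(m=120, n_train=90, n_test=45, r=3, signature_size=15,
                          outcome_genes=4, seed=11)
    return generate_cohorts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_expr(values, prefix_g="g", prefix_s="s"):
    values = np.asarray(values, float)
    m, n = values.shape
    return ExpressionMatrix(
        [f"{prefix_g}{i}" for i in range(m)],
        [f"{prefix_s}{j}" for j in range(n)],
        values,
    )
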