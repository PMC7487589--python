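import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_state():
    """A tiny, fully specified model state with nontrivial covariates."""
    from gnbfactor.model import CovariateSet, ModelState

    rng = np.random.default_rng(5)
    V, J, P, Q, K = 6, 4, 2, 2, 3
    cov = CovariateSet(X=rng.standard_normal((J, P)), Z=rng.standard_normal((V, Q)))
    state = ModelState(
        r=rng.gamma(2.0, 0.5, size=J),
        beta=rng.standard_normal((V, P)) * 0.5,
        delta=rng.standard_normal((J, Q)) * 0.5,
        phi=rng.standard_normal((V, K)) * 0.5,
        theta=rng.standard_normal((J, K)) * 0.5,
        alpha=np.ones(P),
        eta=np.ones(Q),
        gamma=np.ones(K),
        h=1.0,
    )
    return state, cov
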