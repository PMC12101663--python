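import numpy as np
import pytest

from adaptref import LongitudinalSeries, PopulationModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_model():
    """Hand-built population model (mu=5, tau2=1, pooled sigma2=1)."""
    return PopulationModel(
        mu=5.0,
        tau2=1.0,
        sigma2_by_subject={"a": 1.0, "b": 1.0},
        sigma2_pooled=1.0,
        posterior_by_subject={"a": (5.0, 0.5), "b": (5.0, 0.5)},
        loglik_trace=[-10.0, -9.0],
        converged=True,
        n_iter=2,
    )


@pytest.fixture
def normal_collection(rng):
    """20 subjects x 30 occasions from the generating model (mu=5, tau=1, sigma=0.5)."""
    out = []
    for i in range(20):
        mu_i = 5.0 + rng.standard_normal()
        out.append(
            LongitudinalSeries(
                subject_id=f"s{i}", values=mu_i + 0.5 * rng.standard_normal(30)
            )
        )
    return out
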