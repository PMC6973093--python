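import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ratescape.gls import RegressionSpec
from ratescape.simulate import SimulationConfig, simulate_dataset, simulate_tree
from ratescape.tree import parse_newick
from ratescape.vr import ChainSettings, PosteriorTrace

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_ess_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="effective sample sizes")
        warnings.filterwarnings("ignore", message="zero-length terminal")
        yield


@pytest.fixture(scope="session")
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def small_dataset():
    """30-tip simulated dataset without planted structure."""
    return simulate_dataset(SimulationConfig(n_tips=30, seed=7))


@pytest.fixture(scope="session")
def spec():
    return RegressionSpec()


def make_trace(tree, r_draws, sigma2=None, beta=None):
    """PosteriorTrace from explicit per-branch scalar draws (S x B)."""
    r = np.asarray(r_draws, float)
    S = r.shape[0]
    return PosteriorTrace(
        beta=np.tile(np.array([[-2.0, 0.67]]), (S, 1)) if beta is None else np.asarray(beta),
        sigma2=np.full(S, 0.05) if sigma2 is None else np.asarray(sigma2),
        r=r,
        loglik=np.zeros(S),
        coef_names=["(intercept)", "log_body"],
        tree=tree,
        settings=ChainSettings(iterations=2, burn_in=1, thin=1),
    )


@pytest.fixture
def trace_factory():
    return make_trace
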