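import numpy as np
import pytest

from gssrm import (
    CommunityConfig,
    McmcConfig,
    ModelSpec,
    balanced_design,
    build_design,
    fit,
    simulate_community,
    simulate_network,
)
from gssrm.inference import default_experiment_parameters


@pytest.fixture(scope="session")
def small_community():
    """A compact synthetic village used across covariate tests."""
    cfg = CommunityConfig(
        n_households=8,
        target_adults=30,
        founder_couples=4,
        seed=42,
    )
    return simulate_community(cfg)


@pytest.fixture(scope="session")
def small_design(small_community):
    return build_design(small_community, model_id=5)


@pytest.fixture(scope="session")
def experiment_params():
    return default_experiment_parameters()


@pytest.fixture(scope="session")
def small_fit(experiment_params):
    """A quick full-model fit on simulated data, shared by property tests."""
    design = balanced_design(8, 3)
    dataset = simulate_network(design, experiment_params, np.random.default_rng(2))
    posterior = fit(
        dataset,
        ModelSpec(model_id=1),
        McmcConfig(chains=2, warmup=300, draws=300, seed=5),
        check_convergence=False,
    )
    return posterior
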