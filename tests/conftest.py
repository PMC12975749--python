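import numpy as np
import pandas as pd
import pytest

from cwmitv import (Scenario, compute_species_means, cwm_triple,
                    generate_community, generate_environment, generate_traits)


@pytest.fixture(scope="session")
def small_scenario():
    """A fast 6x6-plot, 12-species study used by most unit tests."""
    return Scenario(n_plots_x=6, n_plots_y=6, n_species=12, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    env = generate_environment(small_scenario)
    community = generate_community(env, small_scenario)
    traits = generate_traits(env, community, small_scenario)
    return env, community, traits


@pytest.fixture(scope="session")
def small_triple(small_bundle):
    _, community, traits = small_bundle
    means = compute_species_means(traits)
    return cwm_triple(community, means)


def random_triple(rng: np.random.Generator, n_plots: int = 10):
    """A CwmTriple built from random fixed and intravar series, with the
    specific series defined by the identity specific = fixed + intravar."""
    from cwmitv import CwmTriple
    plots = [f"p{i}" for i in range(n_plots)]
    fixed = pd.DataFrame({"T": rng.normal(10, 3, n_plots)}, index=plots)
    intravar = pd.DataFrame({"T": rng.normal(0, 2, n_plots)}, index=plots)
    return CwmTriple(fixed=fixed, specific=fixed + intravar, intravar=intravar)
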