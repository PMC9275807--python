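import numpy as np
import pytest

import electromotor as em


@pytest.fixture(scope="session")
def reference():
    """The shipped reference configuration bundle."""
    return em.load_reference_config()


@pytest.fixture(scope="session")
def network(reference):
    return reference.network


@pytest.fixture(scope="session")
def protocols(reference):
    return reference.protocols.build_all()


@pytest.fixture(scope="session")
def targets(reference):
    return em.generate_all_targets(rng_seed=1, settings=reference.generator)


@pytest.fixture(scope="session")
def small_grid(network, protocols, targets):
    """A reduced (5x5) robustness grid on the reference configuration,
    shared by the robustness and acceptance tests."""
    from electromotor import robustness as rob

    offsets = np.array([-0.5, -0.25, 0.0, 0.25, 0.5])
    return rob.run_grid(network, protocols, targets, seed=1, offsets=offsets)
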