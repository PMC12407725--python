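import numpy as np
import pytest

import combatpredict as cp


@pytest.fixture(scope="session")
def small_input():
    """10 sites x 20 features with all effect types present."""
    spec = cp.SimulationSpec(n_sites=10, n_features=20, site_sizes=(4, 12), seed=42)
    return cp.generate_combat_data(spec)


@pytest.fixture(scope="session")
def small_fit(small_input):
    inp, _ = small_input
    return cp.CombatModel(inp).fit()


@pytest.fixture(scope="session")
def small_fit_no_eb(small_input):
    inp, _ = small_input
    return cp.CombatModel(inp).fit(eb=False)
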