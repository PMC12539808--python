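import numpy as np
import pandas as pd
import pytest

from pcindex import VariableSpec, VariableTable, WeightScheme
from pcindex.simulate import SimulationConfig, simulate_species


def random_table(rng, n_species=None, n_threats=None, n_modifiers=None):
    """A random valid table with mixed directions/transforms, plus weights."""
    n_species = n_species or int(rng.integers(3, 7))
    n_threats = n_threats if n_threats is not None else int(rng.integers(1, 4))
    n_modifiers = (
        n_modifiers if n_modifiers is not None else int(rng.integers(0, 3))
    )
    ids = pd.Index([f"s{i}" for i in range(n_species)], name="species_id")
    specs, cols = [], {}
    for i in range(n_threats):
        name = f"t{i}"
        specs.append(
            VariableSpec(
                name,
                "threat",
                rng.choice(["direct", "inverted"]),
                rng.choice(["log1p", "none"]),
            )
        )
        cols[name] = rng.uniform(0, 10, n_species)
    for j in range(n_modifiers):
        name = f"v{j}"
        specs.append(
            VariableSpec(
                name,
                "modifier",
                rng.choice(["direct", "inverted"]),
                rng.choice(["log1p", "none"]),
            )
        )
        cols[name] = rng.uniform(0, 100, n_species)
    table = VariableTable(pd.DataFrame(cols, index=ids), specs)
    weights = WeightScheme(
        threat_weights={f"t{i}": float(rng.uniform(0.2, 5)) for i in range(n_threats)},
        interaction_weights={
            (f"t{i}", f"v{j}"): float(rng.uniform(0.2, 5))
            for i in range(n_threats)
            for j in range(n_modifiers)
        },
    )
    return table, weights


@pytest.fixture(scope="session")
def community():
    """A mid-sized deterministic synthetic community shared across tests."""
    return simulate_species(SimulationConfig(n_species=200, n_regions=12, seed=11))


@pytest.fixture(scope="session")
def community_results(community):
    from pcindex import ProactiveConservationIndex

    return ProactiveConservationIndex(community.table).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
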