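import numpy as np
import pandas as pd
import pytest

import coralstress as cs


@pytest.fixture(scope="session")
def default_config():
    return cs.DesignConfig()


@pytest.fixture(scope="session")
def default_design(default_config):
    return cs.generate_design(default_config)


@pytest.fixture(scope="session")
def fragments(default_design):
    """Default design with simulated condition outcomes (fixed seed)."""
    return cs.simulate_condition_outcomes(default_design, seed=11)


@pytest.fixture(scope="session")
def biomarker_matrix(fragments):
    """Simulated biomarker matrix for the surviving cells (fixed seed)."""
    return cs.simulate_biomarkers(fragments, seed=22, on_shortfall="all")


@pytest.fixture(scope="session")
def sensitivity_map(default_config):
    return {a.name: a.sensitivity for a in default_config.species_archetypes}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_records(counts: dict[str, int], species="sp", temperature=26,
                 predation="no_lesion") -> pd.DataFrame:
    """Fragment records for one design cell with given category counts."""
    rows = []
    for cat, n in counts.items():
        for _ in range(n):
            rows.append(
                {"species": species, "temperature": temperature,
                 "predation": predation, "condition": cat}
            )
    return pd.DataFrame(rows)
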