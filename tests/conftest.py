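import numpy as np
import pandas as pd
import pytest

from geoimpute import filter_cases, generate_study, scenario_presets


@pytest.fixture(scope="session")
def kane_study():
    """One generated kane_like study shared across tests (seed 1)."""
    return generate_study(scenario_presets(seed=1)["kane_like"])


@pytest.fixture(scope="session")
def kane_staged(kane_study):
    staged, _ = filter_cases(kane_study.cases)
    return staged


@pytest.fixture(scope="session")
def peoria_study():
    return generate_study(scenario_presets(seed=1)["peoria_like"])


@pytest.fixture()
def toy_blocks():
    """Two zones, three + two blocks, populations only in one subgroup."""
    return pd.DataFrame({
        "block_id": ["b1", "b2", "b3", "b4", "b5"],
        "zone_id": ["z1", "z1", "z1", "z2", "z2"],
        "x": [0.0, 1000.0, 2000.0, 5000.0, 6000.0],
        "y": [0.0, 0.0, 0.0, 0.0, 0.0],
        "pop_nb_lt50": [30, 50, 20, 4, 6],
        "pop_nb_50to69": [10, 10, 10, 5, 5],
        "pop_nb_ge70": [0, 0, 0, 0, 0],
        "pop_b_lt50": [0, 0, 0, 0, 0],
        "pop_b_50to69": [0, 0, 0, 0, 0],
        "pop_b_ge70": [0, 0, 0, 0, 0],
    })


def make_cases(zone_ids, ages=None, races=None, stages=None, years=None):
    n = len(zone_ids)
    return pd.DataFrame({
        "case_id": [f"c{i}" for i in range(n)],
        "zone_id": zone_ids,
        "age": ages if ages is not None else [45] * n,
        "race": races if races is not None else ["nonblack"] * n,
        "sex": ["F"] * n,
        "stage": stages if stages is not None else [2] * n,
        "year": years if years is not None else [2000] * n,
    })


@pytest.fixture()
def case_factory():
    return make_cases
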