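import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from starhelp import datamodel, recip
from starhelp.synthpop import SimConfig, simulate_population

logging.getLogger("starhelp").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but realistic simulated study shared across test modules."""
    return simulate_population(SimConfig(seed=42, n_seasons=8, n_groups=4,
                                         founders_per_group=(8, 14)))


@pytest.fixture(scope="session")
def small_table(small_dataset):
    ds = small_dataset
    presence = datamodel.presence_from_individuals(ds.individuals)
    table, _ = datamodel.build_analysis_table(
        ds.ledger, presence, ds.nests, ds.individuals, relatedness=ds.relatedness
    )
    return recip.attach_reciprocal(table, ds.ledger, ds.nests, mode="atemporal")


@pytest.fixture()
def toy_inputs(tmp_path):
    """Three-visit toy CSV bundle exercising the documented file schemas."""
    obs = pd.DataFrame(
        {
            "helper_id": ["H1", "H2", "H1"],
            "nest_id": ["N1", "N1", "N2"],
            "day": [5, 5, 9],
            "help_minutes": [10, 3, 7],
        }
    )
    nests = pd.DataFrame(
        {
            "nest_id": ["N1", "N2"],
            "group": ["G1", "G1"],
            "season": [1, 1],
            "mother_id": ["M1", "M2"],
            "father_id": ["F1", "F1"],
        }
    )
    individuals = pd.DataFrame(
        {
            "id": ["H1", "H2", "M1", "F1", "M2"],
            "sex": ["male", "female", "female", "male", "female"],
            "dispersal": ["resident", "immigrant", "immigrant", "resident", "immigrant"],
            "group": ["G1"] * 5,
            "first_season": [1] * 5,
            "last_season": [2] * 5,
        }
    )
    exposure = pd.DataFrame(
        {
            "nest_id": ["N1", "N2"],
            "day": [5, 9],
            "exposure_minutes": [120.0, 60.0],
        }
    )
    paths = {}
    for name, df in [
        ("observations.csv", obs),
        ("nests.csv", nests),
        ("individuals.csv", individuals),
        ("exposure.csv", exposure),
    ]:
        p = tmp_path / name
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
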