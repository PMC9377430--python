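import numpy as np
import pandas as pd
import pytest

from greenrisk.geography import generate_lattice
from greenrisk.simulate import (SimulationTruth, simulate_counts,
                                simulate_covariates, simulate_populations)


@pytest.fixture(scope="session")
def lattice_2x2():
    return generate_lattice(2, 2)


@pytest.fixture(scope="session")
def lattice_10x14():
    return generate_lattice(10, 14)


@pytest.fixture(scope="session")
def lattice_3x3():
    return generate_lattice(3, 3)


@pytest.fixture(scope="session")
def toy_stratum_table():
    """Two regions, one stratum: O = (10, 30), pop = (1000, 1000)."""
    return pd.DataFrame({
        "region_id": ["a", "b"],
        "sex": ["male", "male"],
        "age_group": ["0-19", "0-19"],
        "population": [1000, 1000],
        "observed": [10, 30],
    })


def make_synthetic_stratum(geog, *, beta=(0.0, -4.544, 0.0, 0.0, 0.0, 0.0),
                           sigma_u=0.1, sigma_s=0.5, rep=0,
                           sex="male", age_group="20-44"):
    """One stratum's (X, y, E) from the generative model, after internal
    standardization — the workhorse input for model-recovery tests."""
    from greenrisk.standardize import expected

    cov = simulate_covariates(geog, seed=1000 + rep)
    pop = simulate_populations(geog, seed=2000 + rep)
    truth = SimulationTruth(beta=tuple(beta), sigma_u=sigma_u,
                            sigma_s=sigma_s, seed=3000 + rep)
    tab = simulate_counts(geog, cov, pop, truth).drop(columns=["expected"])
    we = expected(tab)
    ids = list(geog.region_ids)
    sub = we[(we["sex"] == sex) & (we["age_group"] == age_group)]
    sub = sub.set_index("region_id").loc[ids]
    X = cov.set_index("region_id").loc[ids, ["X1", "X2", "X3", "X4", "X5"]]
    return (X.to_numpy(float), sub["observed"].to_numpy(float),
            sub["expected"].to_numpy(float))
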