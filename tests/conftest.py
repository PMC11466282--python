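import numpy as np
import pandas as pd
import pytest

from dvomics.simulate import (
    SimConfig,
    simulate_ppi_ontology,
    simulate_proteome,
)


@pytest.fixture(scope="session")
def noise_free_config():
    """Zero measurement noise, no dropout: the linear model holds exactly."""
    return SimConfig(
        n_entities=400,
        seed=11,
        noise_sd_bio=0.0,
        noise_sd_tech=0.0,
        dropout_log2_threshold=-np.inf,
    )


@pytest.fixture(scope="session")
def noise_free_proteome(noise_free_config):
    return simulate_proteome(noise_free_config)


@pytest.fixture(scope="session")
def annotated_graph():
    return simulate_ppi_ontology(100, 30, seed=5)


def make_matrix(values: dict, genotypes=("WT", "D", "L", "Vtl", "Vsp")):
    """Small intensity matrix from {entity: {(genotype, bio, tech): value}}."""
    cols = sorted({k for row in values.values() for k in row})
    data = {
        e: [row.get(c, np.nan) for c in cols] for e, row in values.items()
    }
    return pd.DataFrame.from_dict(
        data,
        orient="index",
        columns=pd.MultiIndex.from_tuples(
            cols, names=["genotype", "bio_rep", "tech_rep"]
        ),
    ).rename_axis("entity")
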