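import numpy as np
import pandas as pd
import pytest

from karyotme import (
    CopyNumberProfile,
    ExpressionMatrix,
    PlantedGene,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """One cohort with a planted immune-cold gain effect on 1p."""
    config = SimulationConfig(
        seed=11,
        n_samples=300,
        planted_is_effects=[("1p", "gain", 1.0)],
        planted_celltype_effects=[("1p", "nk", -2.0)],
        planted_genes=[PlantedGene("3pG000", 1.5, 0.8),
                       PlantedGene("2qG000", 1.5, -0.8)],
        planted_survival_effects=[("1p", "gain", np.log(2.0))],
    )
    return simulate_cohort(config)


@pytest.fixture
def toy_profile():
    values = pd.DataFrame(
        [[0.25, -0.25], [0.2, 0.0], [np.nan, 0.5]],
        index=["S1", "S2", "S3"],
        columns=["1p", "9q"],
    )
    return CopyNumberProfile(level="arm", values=values)


@pytest.fixture
def small_expression():
    rng = np.random.default_rng(5)
    genes = ["CD247", "CD2", "CD3E", "GZMH", "NKG7", "PRF1", "GZMK", "OTHER1"]
    samples = [f"S{i}" for i in range(20)]
    return ExpressionMatrix(pd.DataFrame(
        rng.uniform(0, 100, (20, len(genes))), index=samples, columns=genes
    ))
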