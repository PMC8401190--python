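import numpy as np
import pandas as pd
import pytest

from slforest.io_depmap import OmicsMatrix
from slforest.synthetic_data import PlantedPair, SimConfig, simulate


def make_matrix(rows, samples, genes, kind="dependency"):
    data = pd.DataFrame(np.asarray(rows, dtype=float), index=list(samples), columns=list(genes))
    return OmicsMatrix(data=data, kind=kind)


@pytest.fixture
def tiny_dependency():
    return make_matrix(
        [[-1.0, 0.1], [-0.9, 0.9], [-1.1, 0.5]], ["L1", "L2", "L3"], ["ESS", "VAR"]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by several test modules.

    One mutation pair (M001 -> T01, strong positive) and one expression
    pair (E001 -> T02, strong negative); one essential target (T05).
    """
    cfg = SimConfig(
        n_samples=160,
        n_targets=5,
        n_mut_features=8,
        n_expr_features=8,
        planted_pairs=[
            PlantedPair("T01", "M001", "mutation", 2.5),
            PlantedPair("T02", "E001", "expression", 2.5),
        ],
        mutation_frequency=0.2,
        essential_fraction=0.2,
        seed=11,
    )
    return simulate(cfg)
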