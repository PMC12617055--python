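import numpy as np
import pandas as pd
import pytest

from sexbias.io import CountMatrix
from sexbias.simulate import SimConfig, simulate_dataset


@pytest.fixture
def toy_counts() -> CountMatrix:
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 200, size=(6, 4))
    return CountMatrix(
        [f"g{i}" for i in range(6)], [f"s{j}" for j in range(4)], counts
    )


@pytest.fixture(scope="session")
def sim_small():
    """One ZW species, 1200 genes, 3 tissues, 3 replicates/sex (session-wide)."""
    cfg = SimConfig(
        n_genes=1200,
        tissues=("gonad", "brain", "liver"),
        species_specs=[("zw_sp", "ZW", ("LG05",))],
        seed=1234,
    )
    cm, samples, annotation, truth = simulate_dataset(cfg)
    return cfg, cm, samples, annotation, truth


@pytest.fixture
def toy_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "chromosome": ["LG01", "LG01", "LG05", "LG05", "MT", "scaffold_001"],
            "start": [0, 2000, 0, 5000, 0, 0],
            "end": [1000, 3500, 2000, 6000, 500, 800],
        }
    )
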