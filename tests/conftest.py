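import numpy as np
import pandas as pd
import pytest

from sproutval.synthetic_data import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def qc_fixture():
    """38-marker panel with the exact contamination composition:

    6 markers with >= 70% missing calls, 2 with gross heterozygosity,
    7 monomorphic, 1 at MAF 0.02, 22 clean (contamination realized as
    exact counts so the composition is seed-independent).
    """
    cfg = SimulationConfig(rng_seed=7, exact_counts=True)
    matrix, meta, truth = simulate_panel(cfg)
    return matrix, meta, truth


def make_gi_frame(values: np.ndarray, env: str = "E1") -> pd.DataFrame:
    """Long gi table from a genotype x replicate array."""
    a, k = values.shape
    rows = [
        {"genotype_id": f"G{i + 1:02d}", "environment_id": env,
         "replicate": j + 1, "gi": float(values[i, j])}
        for i in range(a) for j in range(k)
    ]
    return pd.DataFrame(rows)
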