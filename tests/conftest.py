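import numpy as np
import pandas as pd
import pytest

import necromass as nm


@pytest.fixture(scope="session")
def default_dataset() -> nm.SyntheticDataset:
    """One default synthetic experiment (48 samples), shared read-only."""
    return nm.simulate_dataset(nm.SimulationConfig(seed=11))


@pytest.fixture()
def peak_table() -> pd.DataFrame:
    """Three-sample wide peak table with hand-checkable areas."""
    return pd.DataFrame(
        {
            "area_glcn": [1000.0, 2000.0, 0.0],
            "area_galn": [500.0, 500.0, 500.0],
            "area_murn": [1000.0, 500.0, 1000.0],
            "area_inositol": [1000.0, 1000.0, 1000.0],
            "mass_inositol_ug": [100.0, 50.0, 100.0],
            "dry_mass_g": [1.0, 1.0, 1.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )


def euclidean_distance_frame(points: np.ndarray, ids=None) -> pd.DataFrame:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(points))
    ids = ids if ids is not None else [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(d, index=ids, columns=ids)
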