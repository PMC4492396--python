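import numpy as np
import pandas as pd
import pytest

from devnet import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """Default-design synthetic dataset at reduced probe count, with the
    planted outlier array. Session-scoped: treat as read-only."""
    cfg = synthetic.default_outlier_config(seed=7)
    cfg.n_probes = 900
    return synthetic.generate_dataset(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_meta():
    """4 ages x 2 regions x 2 animals = 16 samples."""
    rows = []
    for age in (0, 3, 12, 48):
        for region in ("mPFC", "HIP"):
            for animal in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{region}_{age}_{animal}",
                        "region": region,
                        "age_months": age,
                        "animal_id": f"A{animal}",
                    }
                )
    return pd.DataFrame(rows)
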