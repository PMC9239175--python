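import numpy as np
import pandas as pd
import pytest

from rhizonet import CommunityConfig, OtuTable, generate_community


@pytest.fixture
def small_table() -> OtuTable:
    counts = pd.DataFrame(
        {
            "S1": [6, 2, 0, 4],
            "S2": [2, 2, 4, 1],
            "S3": [1, 0, 7, 3],
        },
        index=["OTU1", "OTU2", "OTU3", "OTU4"],
    )
    tax = pd.Series(
        ["Alphaproteobacteria;Bradyrhizobium"] * 4,
        index=counts.index,
    )
    return OtuTable(counts, taxonomy=tax)


@pytest.fixture
def metadata_frame() -> pd.DataFrame:
    treatments = ["FO", "FOE", "FOP", "FOPE", "FON", "FOEN", "FOPN", "FOPEN"] * 3
    n = len(treatments)
    return pd.DataFrame(
        {
            "treatment": treatments,
            "nematode_added": [t.endswith("N") for t in treatments],
            "bacterivore_density": np.linspace(50, 350, n),
            "total_nematode_density": np.linspace(120, 800, n),
            "phoD_abundance": np.linspace(5e6, 3e7, n),
        },
        index=pd.Index([f"S{i + 1:02d}" for i in range(n)], name="sample_id"),
    )


@pytest.fixture(scope="session")
def default_community():
    """One deterministic draw from the default generator, shared across tests."""
    cfg = CommunityConfig(seed=42)
    return generate_community(cfg)
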