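import numpy as np
import pandas as pd
import pytest

from methatlas.synthetic import SimulationConfig, planted_dnam_reference


@pytest.fixture
def small_cfg():
    """Down-scaled study: 6 types, 10 markers each, quick everywhere."""
    return SimulationConfig(
        seed=7,
        markers_per_type=10,
        n_background_genes=40,
        cells_per_type=30,
        n_mixtures=50,
        nuclei_per_type=80,
    )


@pytest.fixture
def small_reference(small_cfg):
    return planted_dnam_reference(small_cfg)


@pytest.fixture
def probe_betas():
    """Tiny probe-level beta matrix with a missing value."""
    return pd.DataFrame(
        {
            "s1": [0.2, 0.4, 0.6, np.nan, 0.5],
            "s2": [0.1, 0.3, 0.8, 0.9, np.nan],
        },
        index=["p1", "p2", "p3", "p4", "p5"],
    )


@pytest.fixture
def simple_manifest():
    return pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "p3", "p4", "p5"],
            "gene": ["G", "G", "H", "J", "H"],
            "region_group": ["TSS200", "TSS200", "FirstExon", "Other", "FirstExon"],
        }
    )
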