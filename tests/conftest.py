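import numpy as np
import pandas as pd
import pytest

from streamnets import synth
from streamnets.config import SimulationConfig


@pytest.fixture
def traits():
    """Small hand-written trait table covering orders, FFGs, tolerances."""
    return pd.DataFrame(
        {
            "taxon_id": [f"T{i}" for i in range(1, 9)],
            "order": [
                "Ephemeroptera", "Plecoptera", "Trichoptera", "other",
                "other", "Ephemeroptera", "other", "other",
            ],
            "ffg": [
                "collector-gatherer", "shredder", "scraper", "predator",
                "filter-collector", "collector-gatherer", "unknown", "piercer",
            ],
            "tolerance": [2.0, 4.0, 5.0, 6.0, 8.0, 3.0, 1.0, 9.0],
        }
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_taxa=40, n_huc8=2, default_stratum_size=18)


@pytest.fixture(scope="session")
def small_world(small_config):
    """One generated dataset shared by read-only tests."""
    taxa = synth.generate_taxa(small_config)
    samples, counts, truth = synth.generate_samples(small_config, taxa)
    wells, catchments, membership = synth.generate_wells(samples, small_config)
    return {
        "config": small_config,
        "taxa": taxa,
        "samples": samples,
        "counts": counts,
        "truth": truth,
        "wells": wells,
        "catchments": catchments,
        "membership": membership,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
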