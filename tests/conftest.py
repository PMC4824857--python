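import numpy as np
import pandas as pd
import pytest

from srmquant.syndata import SimConfig, simulate_truth, simulate_srm


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=60, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_peaks(small_truth, small_config):
    peaks, transitions = simulate_srm(small_truth, small_config)
    return peaks, transitions


@pytest.fixture()
def rng():
    return np.random.default_rng(20160110)


def make_replicate_rows(**overrides) -> pd.DataFrame:
    """A clean 4-replicate single-spike scored table for one peptide."""
    base = {
        "peptide_id": ["P1"] * 4,
        "protein_group_id": ["G1"] * 4,
        "replicate": [1, 2, 3, 4],
        "spike_label": ["medium"] * 4,
        "spike_amount_mol": [1e-15] * 4,
        "light_area": [1e5] * 4,
        "heavy_area": [1e5] * 4,
        "ratio": [1.0] * 4,
        "sn": [20.0] * 4,
        "heavy_sn": [20.0] * 4,
        "noise_area": [100.0] * 4,
        "q_value": [0.001] * 4,
        "cells_on_column": [2e5] * 4,
    }
    base.update(overrides)
    return pd.DataFrame(base)
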