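import numpy as np
import pandas as pd
import pytest

import xdprescue as xr


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete simulated experiment with ground truth."""
    cfg = xr.SimulationConfig(
        n_genes=400, treatments=("ASO01", "ASO02"), seed=101
    )
    counts, sheet, truth = xr.simulate_experiment(cfg)
    return cfg, counts, sheet, truth


@pytest.fixture()
def two_group_sheet():
    """Minimal untreated 6-vs-6 sample sheet."""
    rows = []
    for i in range(6):
        rows.append((f"C{i}", f"sc{i}", "CON", "none", "none", "", "b1"))
    for i in range(6):
        rows.append((f"X{i}", f"sx{i}", "XDP", "naive", "none", "", "b1"))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "subject_id", "genotype", "edit_status",
                 "treatment", "pair_id", "batch"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
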