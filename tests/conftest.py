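import numpy as np
import pandas as pd
import pytest

import strainexpr as sx


@pytest.fixture(scope="session")
def fixture_tables():
    return sx.load_fixture()


@pytest.fixture(scope="session")
def small_world():
    """One simulated assay world shared by read-only tests."""
    cfg = sx.SimulationConfig(n_strains=8, tech_reps=2, n_genes=10, h2=0.6, seed=42)
    matrix, design, truth = sx.simulate_signals(cfg)
    return cfg, matrix, design, truth


@pytest.fixture()
def toy_design():
    table = pd.DataFrame(
        {
            "strain": ["A", "A", "B", "B", "C", "C"],
            "sex": ["F", "M", "F", "M", "F", "M"],
        },
        index=pd.Index([f"i{j}" for j in range(6)], name="individual"),
    )
    return sx.SampleDesign(table)


def make_signal_matrix(values, sample_ids, is_background, probes=None):
    """Assemble a SignalMatrix from plain arrays (wells × probes)."""
    values = np.asarray(values, dtype=float)
    n_wells, n_probes = values.shape
    probes = probes or [f"P{j}" for j in range(n_probes)]
    wells = pd.DataFrame(
        {
            "sample_id": [s if s is not None else pd.NA for s in sample_ids],
            "strain": pd.NA,
            "sex": pd.NA,
            "tech_rep": pd.NA,
            "is_background": is_background,
        },
        index=pd.Index([f"w{j}" for j in range(n_wells)], name="well_id"),
    )
    signals = pd.DataFrame(values, index=wells.index, columns=probes)
    return sx.SignalMatrix(signals, wells)
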