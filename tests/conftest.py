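import numpy as np
import pandas as pd
import pytest

from asorescue.simulate import SimulationConfig, baseline_arms, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A compact full-design cohort shared across tests (2k genes,
    60 up / 120 down signature genes, all six arms).  The line-program
    loading is raised so that, as in the full-scale design, cell-line
    variability dominates the first principal component with the
    genotype/dosage axis on the second."""
    cfg = SimulationConfig(
        n_genes=2000,
        n_dosage_up=60,
        n_dosage_down=120,
        line_axis_sd=1.6,
        library_size_range=(5e6, 7e6),
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def baseline_cohort():
    """Control-only cohort (naive + scramble) for DE-level tests."""
    cfg = SimulationConfig(
        n_genes=2000,
        n_dosage_up=60,
        n_dosage_down=120,
        arms=baseline_arms(),
        library_size_range=(5e6, 7e6),
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def tiny_counts():
    from asorescue.datamodel import CountMatrix

    return CountMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        np.array([[0, 1], [2, 3], [4, 5]]),
    )


@pytest.fixture()
def simple_design():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "genotype": ["affected", "unaffected"],
            "cell_line": ["L1", "L2"],
            "treatment": ["naive", "naive"],
            "aso_sequence": [None, None],
            "dose": [0.0, 0.0],
        }
    )
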