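import numpy as np
import pytest

from compenseq import CountTable, SampleSheet, SimulationConfig, simulate_counts


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(
        ["g1", "g2", "g3"], ["s1", "s2"], np.array([[0, 1], [2, 3], [4, 5]])
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    """A quick three-strain simulation: 400 genes at reduced depth."""
    return SimulationConfig(
        n_genes=400,
        replicates={"W": 4, "KM": 3, "ZERO": 4},
        lib_size_range=(300_000, 450_000),
        seed=101,
    )


@pytest.fixture(scope="session")
def simulated_dataset():
    """A mid-sized dataset shared by read-only tests (2000 genes, n=4)."""
    cfg = SimulationConfig(
        n_genes=2000,
        replicates={"W": 4, "KM": 4, "ZERO": 4},
        lib_size_range=(1_500_000, 2_200_000),
        effect_size_logfc=2.0,
        seed=2024,
    )
    return simulate_counts(cfg)


@pytest.fixture
def three_group_sheet() -> SampleSheet:
    return SampleSheet(
        {
            "W_1": "W",
            "W_2": "W",
            "KM_1": "KM",
            "KM_2": "KM",
            "Z_1": "0",
            "Z_2": "ZERO",
        }
    )
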