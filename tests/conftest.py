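import numpy as np
import pandas as pd
import pytest

from clpnkit import (FitConfig, SimulationConfig, TwoWavePanel, load_codebook,
                     load_table2_fixture, make_true_network, simulate_panel)


@pytest.fixture(scope="session")
def codebook():
    return load_codebook()


@pytest.fixture(scope="session")
def fixture_matrix():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def partition(codebook):
    return codebook.partition()


def build_panel(n=10, codebook=None, seed=0, completer=None):
    """Small hand-rolled valid panel for I/O and validation tests."""
    codebook = codebook or load_codebook()
    rng = np.random.default_rng(seed)
    completer = (np.ones(n, dtype=bool) if completer is None
                 else np.asarray(completer, dtype=bool))
    data = {
        "participant_id": [f"p{i}" for i in range(n)],
        "age": rng.integers(18, 70, n).astype(float),
        "sex": rng.integers(0, 2, n),
        "completer": completer,
    }
    legal = np.array([0] + list(range(3, 14)), dtype=float)
    for code in codebook.codes:
        data[f"{code}_T1"] = rng.choice(legal, n)
        t2 = rng.choice(legal, n)
        data[f"{code}_T2"] = np.where(completer, t2, np.nan)
    return TwoWavePanel(pd.DataFrame(data), codebook)


@pytest.fixture
def small_panel(codebook):
    return build_panel(12, codebook, seed=1,
                       completer=[True] * 10 + [False] * 2)


@pytest.fixture(scope="session")
def sim_panel_32():
    """Study-scale simulated panel shared by slower estimation tests."""
    truth = make_true_network(seed=1)
    return truth, simulate_panel(truth, SimulationConfig(), seed=2)


@pytest.fixture(scope="session")
def quick_config():
    """Reduced lambda grid / folds for tests where full CV depth is not the point."""
    return FitConfig(n_lambda=40, n_folds=5)
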