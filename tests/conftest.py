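import numpy as np
import pandas as pd
import pytest

from fuzzyforests import (
    SimConfig,
    ModuleSpec,
    build_network,
    recode_good_health,
)
from fuzzyforests.data import encode_features
from fuzzyforests.synthetic_survey import generate_dataset, generate_train_test


def small_sim_config() -> SimConfig:
    """Desk-scale design: 3 correlated blocks, 8 independent items,
    3 planted signals, the default language factor."""
    return SimConfig(
        n=400,
        modules=(ModuleSpec(12, 0.7), ModuleSpec(12, 0.6), ModuleSpec(12, 0.7)),
        n_independent=8,
        planted=(("mod1_f01", 1.5), ("mod2_f01", 1.5), ("ind_f01", 1.5)),
    )


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_waves(small_config):
    return generate_train_test(small_config, 7)


@pytest.fixture(scope="session")
def small_xy(small_config):
    table, codebook, truth = generate_dataset(small_config, 7)
    y = recode_good_health(table["general_health"])
    X, parent = encode_features(table, codebook, nominal="codes")
    return X, y, truth


@pytest.fixture(scope="session")
def default_dataset():
    """The packaged default design at full scale (seed 1)."""
    table, codebook, truth = generate_dataset(SimConfig(), 1)
    y = recode_good_health(table["general_health"])
    X, parent = encode_features(table, codebook, nominal="codes")
    return {"table": table, "codebook": codebook, "truth": truth, "X": X, "y": y}


@pytest.fixture(scope="session")
def default_partition(default_dataset):
    return build_network(default_dataset["X"])


@pytest.fixture(scope="session")
def default_stability(default_dataset, default_partition):
    """50 stage-2 repeats on the default design (stage 1 shared) — the
    stability experiment several selection tests read from."""
    from fuzzyforests import stability_selection

    return stability_selection(
        default_dataset["X"],
        default_dataset["y"],
        n_runs=50,
        master_seed=1,
        partition=default_partition,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
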