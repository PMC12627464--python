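import numpy as np
import pandas as pd
import pytest

from eaafinger import (
    EAA_PANEL,
    MeasurementTable,
    SimulationConfig,
    TrainingSimConfig,
    simulate_experiment,
    simulate_training,
)


@pytest.fixture
def small_table() -> MeasurementTable:
    """Four consumer rows plus a complete one-replicate diet block."""
    rows = [
        ("m1", "GF", "liver", "Ile", -20.0, 1),
        ("m1", "GF", "liver", "Leu", -25.0, 1),
        ("m2", "CVZ", "liver", "Ile", -19.0, 1),
        ("m2", "CVZ", "liver", "Leu", -24.5, 1),
    ]
    for aa, v in zip(EAA_PANEL, (-21.0, -26.0, -19.0, -26.5, -16.0, -24.0)):
        rows.append(("d1", "diet", "diet", aa, v, 1))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "organ", "amino_acid", "delta13c", "replicate"],
    )
    return MeasurementTable(df)


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    return SimulationConfig(
        f=0.0, analytical_sd=0.0, biological_sd=0.0, n_mice_per_group=3, seed=0
    )


@pytest.fixture
def default_training():
    return simulate_training(TrainingSimConfig(seed=42))


@pytest.fixture
def h0_experiment() -> MeasurementTable:
    return simulate_experiment(SimulationConfig(f=0.0, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
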