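import numpy as np
import pytest

from pdsched import (DayGenConfig, DayRecord, default_population, generate_day,
                     sample_patient)
from pdsched.experiments import generate_cohort
from pdsched.models import ImpulseModelConfig, TrainConfig, train_general


@pytest.fixture(scope="session")
def population():
    return default_population()


@pytest.fixture(scope="session")
def patient(population):
    return sample_patient(population, 3)


@pytest.fixture(scope="session")
def small_days(population):
    """3 virtual patients x 3 medication days on the 10-minute grid."""
    _, days = generate_cohort(population, 3, 3, rng_seed=11)
    return days


@pytest.fixture(scope="session")
def tiny_impulse_model(small_days):
    """A quickly trained small impulse model for rollout/persistence tests."""
    cfg = ImpulseModelConfig(lstm_units=4, hidden_sizes=(8, 8))
    model, _ = train_general(small_days, cfg,
                             TrainConfig(max_epochs=25, patience=20, batch_size=4,
                                         rng_seed=5))
    return model
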