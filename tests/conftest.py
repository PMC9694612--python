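import numpy as np
import pytest

from anisann import (
    DesignSpec,
    EffectsConfig,
    MLPParams,
    ResponseEffects,
    ResponseScaler,
    SplitIndices,
    TrainedModel,
    default_effects,
    encode_design,
    generate_trial,
)
from anisann.design import RESPONSE_NAMES


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def effects():
    return default_effects(0)


@pytest.fixture(scope="session")
def zero_noise_effects():
    base = default_effects(0)
    quiet = {
        name: ResponseEffects(
            intercept=eff.intercept,
            year_effect=eff.year_effect,
            locality_effects=dict(eff.locality_effects),
            fertilization_effects=dict(eff.fertilization_effects),
            noise_sd=0.0,
            nonlinear_gain=eff.nonlinear_gain,
        )
        for name, eff in base.responses.items()
    }
    return EffectsConfig(responses=quiet)


@pytest.fixture(scope="session")
def trial_table(design, effects):
    return generate_trial(design, effects, seed=11)


@pytest.fixture(scope="session")
def encoded(design, trial_table):
    return encode_design(trial_table, design)


def make_random_model(design, seed, scale=0.5):
    """A TrainedModel with random weights — no training, for GA/pipeline tests."""
    rng = np.random.default_rng(seed)
    n_in = design.n_inputs
    params = MLPParams(
        W1=rng.uniform(-scale, scale, (n_in, 6)),
        B1=rng.uniform(-scale, scale, 6),
        W2=rng.uniform(-scale, scale, (6, 30)),
        B2=rng.uniform(-scale, scale, 30),
        hidden_activation="tanh",
        output_activation="identity",
    )
    scaler = ResponseScaler()
    scaler.fit(rng.uniform(0.0, 10.0, (8, 30)))
    n = design.n_records
    split = SplitIndices(
        train=np.arange(0, n, 2),
        validation=np.arange(1, n, 4),
        test=np.arange(3, n, 4),
    )
    return TrainedModel(
        params=params,
        scaler=scaler,
        split=split,
        output_names=list(RESPONSE_NAMES),
        sos={"train": 0.0, "validation": 0.0, "test": 0.0},
        sos_original={"train": 0.0, "validation": 0.0, "test": 0.0},
        performance={"train": 1.0, "validation": 1.0, "test": 1.0},
        loss_trajectory=np.array([0.0]),
        restart_log=[],
        n_iterations=0,
    )


@pytest.fixture
def random_model(design):
    return make_random_model(design, seed=5)
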