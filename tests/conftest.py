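import pytest
from hypothesis import HealthCheck, settings as hyp_settings

hyp_settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("suite")

from htncea import (
    ChartParams,
    CohortSpec,
    CostEffectivenessModel,
    CostInputs,
    DisabilityWeights,
    ModelSettings,
    TransitionParameters,
    generate_cohort,
    generate_life_table,
    generate_risk_chart,
)


@pytest.fixture(scope="session")
def tparams():
    return TransitionParameters()


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def weights():
    return DisabilityWeights()


@pytest.fixture(scope="session")
def costs():
    return CostInputs()


@pytest.fixture(scope="session")
def chart():
    return generate_risk_chart(ChartParams())


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table()


@pytest.fixture(scope="session")
def cohort(chart):
    return generate_cohort(CohortSpec(n=200, seed=99), chart)


@pytest.fixture(scope="session")
def fitted_model():
    """Calibrated synthetic study shared across tests (seeded)."""
    model = CostEffectivenessModel.from_synthetic(seed=20240915)
    return model


@pytest.fixture(scope="session")
def fitted_results(fitted_model):
    return fitted_model.fit()
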