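import dataclasses

import pytest

import hatea
from hatea.scenarios import ScenarioEvaluator

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def fixtures():
    return hatea.load_study_fixtures()


@pytest.fixture(scope="session")
def evaluator(fixtures):
    return ScenarioEvaluator(fixtures)


@pytest.fixture(scope="session")
def endo_train(fixtures):
    """Full train for the selected endogenous option (option 2)."""
    return hatea.build_train(fixtures, 2)


@pytest.fixture(scope="session")
def rec_train(fixtures):
    """Full train for the selected recombinant option (option 5)."""
    return hatea.build_train(fixtures, 5)


@pytest.fixture(scope="session")
def small_design(fixtures):
    """Reduced variation design for fast combinatorial tests."""
    return dataclasses.replace(
        fixtures.design,
        multiplier_levels=(0.5, 1.0, 2.0),
        scale_levels_L=(10.0, 100.0),
        discount_levels=(0.0, 0.4),
        yield_levels=(0.5, 1.0),
        base_scale_L=100.0,
        n_sweep_titers=3,
    )


@pytest.fixture(scope="session")
def oat_results(fixtures, evaluator):
    """Evaluated full OAT design for the endogenous source."""
    scenarios = hatea.oat_scenarios(fixtures.design)
    return evaluator.evaluate_frame(scenarios, "endogenous")
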