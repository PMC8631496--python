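import logging

import pytest
from hypothesis import settings

import pncell

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

logging.getLogger("pncell").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def calibrated_defaults():
    """All 24 shipped relationships with derived θ, plus the scaling factor."""
    rels = pncell.load_default_relationships()
    return pncell.calibrate(rels)


@pytest.fixture(scope="session")
def default_system(calibrated_defaults):
    calibrated, _ = calibrated_defaults
    return pncell.PNSystem(tuple(r for r in calibrated if r.in_pn_system))


@pytest.fixture(scope="session")
def inflammation_relationships(calibrated_defaults):
    calibrated, _ = calibrated_defaults
    return [r for r in calibrated if not r.in_pn_system]


@pytest.fixture(scope="session")
def default_curves():
    return pncell.load_default_curves()


@pytest.fixture(scope="session")
def default_cytokines(inflammation_relationships):
    return pncell.default_cytokine_params(inflammation_relationships)


@pytest.fixture(scope="session")
def preset_environments():
    return {name: pncell.NutrientEnvironment.from_preset(name)
            for name in pncell.ENVIRONMENT_PRESETS}
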