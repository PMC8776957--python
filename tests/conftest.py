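import warnings

import pytest

from forestplots.datagen import SurveyConfig, generate_survey


@pytest.fixture(scope="session")
def default_survey():
    """One full-size survey (3 islands x 3 types x 10 plots), seed 1."""
    return generate_survey(SurveyConfig(seed=1))


@pytest.fixture()
def tiny_config():
    """3 islands x 3 types x 2 plots with a small pool: fast but complete."""
    return SurveyConfig(plots_per_cell=2, species_pool_size=30, seed=7)


@pytest.fixture()
def tiny_survey(tiny_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_survey(tiny_config)
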