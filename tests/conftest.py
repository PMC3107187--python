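import pytest

from epifit.assay_io import effects_relative_to_wt, summarize
from epifit.cross_validation import loo_predict
from epifit.gamma_fit import FitInput, fit
from epifit.synthetic_data import default_config, generate, id11_dataset


@pytest.fixture(scope="session")
def id11():
    return id11_dataset()


@pytest.fixture(scope="session")
def id11_effects(id11):
    return id11.effect_table()


@pytest.fixture(scope="session")
def id11_fit(id11):
    return fit(id11.fit_input())


@pytest.fixture(scope="session")
def id11_loo(id11):
    return loo_predict(id11.fit_input())


@pytest.fixture(scope="session")
def noisefree_config():
    return default_config(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noisefree_data(noisefree_config):
    replicates = generate(noisefree_config)
    effects = effects_relative_to_wt(summarize(replicates), "ID11")
    return FitInput.from_effect_table(effects)


@pytest.fixture(scope="session")
def noisefree_fit(noisefree_data):
    return fit(noisefree_data)
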