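import numpy as np
import pandas as pd
import pytest

from oplur import preprocessing, regional_background
from oplur import synthetic_data as sd


def make_campaign(seed=11, noiseless=False, **overrides):
    kwargs = dict(seed=seed)
    if noiseless:
        kwargs["noise_sd"] = {"OP_DTT": 0.0, "OP_ESR": 0.0}
        kwargs["temporal_effects"] = {"OP_DTT": (0, 0, 0), "OP_ESR": (0, 0, 0)}
    kwargs.update(overrides)
    return sd.generate_campaign(sd.CampaignConfig(**kwargs))


def annual_table(campaign):
    return preprocessing.adjusted_annual_averages(
        campaign.measurements, campaign.reference, campaign.config.blank_mean
    )


def fitting_inputs(campaign, metric, annual=None):
    """(y, augmented predictor table incl. regional estimate) for one metric."""
    if annual is None:
        annual = annual_table(campaign)
    aug = regional_background.add_regional_predictor(
        campaign.predictors, campaign.sites, annual, metric
    )
    y = (
        annual[annual["metric"] == metric]
        .set_index("site_id")["value"]
        .loc[aug.values.index]
    )
    return y, aug


@pytest.fixture(scope="session")
def noiseless_campaign():
    return make_campaign(seed=11, noiseless=True)


@pytest.fixture(scope="session")
def noisy_campaign():
    return make_campaign(seed=11)


@pytest.fixture(scope="session")
def noiseless_annual(noiseless_campaign):
    return annual_table(noiseless_campaign)


@pytest.fixture(scope="session")
def noisy_annual(noisy_campaign):
    return annual_table(noisy_campaign)
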