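import warnings

import pytest

from soilstore import data, synth

# statsmodels MixedLM (used only as a cross-check oracle) chatters about
# boundary fits on small synthetic datasets
warnings.filterwarnings("ignore", message=".*boundary.*")


@pytest.fixture(scope="session")
def fixture_ds() -> data.GradientDataset:
    return data.load_table1_fixture()


@pytest.fixture()
def default_cfg() -> synth.SyntheticConfig:
    return synth.SyntheticConfig(seed=42)


@pytest.fixture()
def noise_free_cfg() -> synth.SyntheticConfig:
    # zero stochastic noise on storage, sites and incubation; the covariate
    # keeps its spread because with a constant PLFA per soil type the
    # group-plus-covariate design is rank deficient (EMMs non-identifiable)
    cfg = synth.SyntheticConfig(
        seed=7,
        plfa_log_sd=0.25,
        site_sd=0.0,
        residual_sd=0.0,
        pde_log_sd=0.0,
        chem_log_sd=0.0,
        incubation_noise_sd=0.0,
    )
    for cls, (mu, _) in cfg.fungal_fraction.items():
        cfg.fungal_fraction[cls] = (mu, 0.0)
    return cfg
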