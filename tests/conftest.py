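import numpy as np
import pytest

from wfscale import (
    DemographyPlan,
    ModelSpec,
    MutationClassMix,
    build_catalog_model,
)
from wfscale.models import FitnessEffectDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20240907)


@pytest.fixture
def neutral_model():
    """Small strictly neutral model (N=200, 50 kb) for fast engine runs."""
    return ModelSpec(
        label="neutral_small",
        L=50_000,
        mu=1.2e-8 * 50,   # theta-equivalent of N=10,000 at N=200: keeps sites plentiful
        r=1.2e-8 * 50,
        mix=MutationClassMix(f_n=1.0, f_b=0.0, f_d=0.0),
        demography=DemographyPlan.for_sizes(200),
    )


@pytest.fixture
def tiny_selected_model():
    """Small model with all three mutation classes present."""
    return ModelSpec(
        label="tiny_full",
        L=100_000,
        mu=1e-7,
        r=1e-7,
        mix=MutationClassMix(f_n=0.25, f_b=0.0375, f_d=0.7125),
        demography=DemographyPlan.for_sizes(100),
        dfe_beneficial=FitnessEffectDistribution(kind="fixed", s_fixed=0.05),
        dfe_deleterious=FitnessEffectDistribution(
            kind="gamma", gamma_mean=-0.0294, gamma_shape=0.184),
    )


@pytest.fixture
def full_model():
    return build_catalog_model("full")
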