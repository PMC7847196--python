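import math

import pytest

from xenopower import GrowthParams, named_params, simulate_study


@pytest.fixture(scope="session")
def pdx_params() -> GrowthParams:
    return named_params("pdx")


@pytest.fixture(scope="session")
def cdx_params() -> GrowthParams:
    return named_params("cdx")


@pytest.fixture(scope="session")
def toy_params() -> GrowthParams:
    """Small, mildly variable population used by oracle-driven tests."""
    return GrowthParams(
        mu1=0.0, mu2=math.log(0.1), sigma1=0.1, sigma2=0.2, sigma3=0.1
    )


@pytest.fixture(scope="session")
def null_study(pdx_params):
    """One simulated two-arm study with no treatment effect."""
    return simulate_study(pdx_params, n_per_arm=10, horizon=14, seed=7)


@pytest.fixture(scope="session")
def effect_study(pdx_params):
    """One simulated study with a strong growth-slowing effect."""
    return simulate_study(
        pdx_params.with_effect(-0.8), n_per_arm=10, horizon=14, seed=42
    )
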