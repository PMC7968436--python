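"""Shared fixtures: fixture world, calibrated world, and a full model fit."""

import pytest

from ssbsim import SSBBanModel, build_fixture_world, build_calibrated_world


@pytest.fixture(scope="session")
def calibrated_world():
    """The calibrated world reproducing the published summary targets."""
    return build_calibrated_world()


@pytest.fixture(scope="session")
def calibrated_fit(calibrated_world):
    """Full-scale fit used by the quantitative acceptance checks."""
    model = SSBBanModel(calibrated_world, n_persons=10_000, n_replicates=50)
    return model.fit(seed=1)


@pytest.fixture()
def fixture_world():
    """One active disease, constant rates, no background mortality."""
    return build_fixture_world()
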