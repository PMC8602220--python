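import numpy as np
import pytest

from ppmopkpd import (
    DEFAULT_ERROR_MODELS,
    FitSettings,
    fit_plasma,
    generate_study,
    study_designs,
    reference_estimates,
)

SEED = 20260929


@pytest.fixture(scope="session")
def ref():
    """Published naive-pooled parameter estimates (generating truth)."""
    return reference_estimates()


@pytest.fixture(scope="session")
def designs():
    return study_designs()


@pytest.fixture(scope="session")
def plasma_ds(ref, designs):
    return generate_study(designs["plasma_single"], ref, seed=SEED)


@pytest.fixture(scope="session")
def tissue_ds(ref, designs):
    single = generate_study(designs["pkpd_single"], ref, seed=SEED + 1)
    repeat = generate_study(designs["pkpd_repeat"], ref, seed=SEED + 2)
    return single.concat(repeat)


@pytest.fixture(scope="session")
def plasma_fit(ref, plasma_ds):
    return fit_plasma(plasma_ds, ref.plasma, FitSettings(n_starts=2, seed=SEED))
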