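import dataclasses

import pytest

from centimix import FitConfig, dpms_preset, generate_cohort, pnhs_preset


@pytest.fixture(scope="session")
def dpms_cohort():
    """One deterministic memory-clinic style cohort (n=840)."""
    return generate_cohort(dpms_preset(), seed=7)


@pytest.fixture(scope="session")
def pnhs_cohort():
    """One deterministic pre-dementia style cohort (n=1600)."""
    return generate_cohort(pnhs_preset(), seed=7)


@pytest.fixture(scope="session")
def default_config():
    return FitConfig(seed=7)


@pytest.fixture(scope="session")
def dpms_fit(dpms_cohort, default_config):
    from centimix import fit_em

    return fit_em(dpms_cohort, default_config)


@pytest.fixture(scope="session")
def pnhs_fit(pnhs_cohort, default_config):
    from centimix import fit_em

    return fit_em(pnhs_cohort, default_config)


def resized(preset, n):
    """A copy of a generator preset with a different cohort size."""
    return dataclasses.replace(preset, n=n)
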