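import dataclasses

import pytest

import memtrain as mt
from memtrain.cohort import GroupValue


@pytest.fixture(scope="session")
def paper_config():
    return mt.paper_defaults()


@pytest.fixture(scope="session")
def paper_cohort(paper_config):
    """One realization of the full published study design."""
    return mt.simulate_cohort(paper_config, seed=11)


@pytest.fixture(scope="session")
def small_config(paper_config):
    """A scaled-down study for fast fitting tests."""
    return dataclasses.replace(
        paper_config,
        n_abab=(12, 14),
        n_baba=(8, 12),
        n_active_ctrl=(2, 3),
        n_passive=(10, 10),
        wordpair_missing_prob=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return mt.simulate_cohort(small_config, seed=5)


def noiseless_config(base):
    """Integer-effect, zero-noise, zero-decay configuration.

    With lambda = 0, integer effects, and no age/sex terms the model mean
    is an integer at every visit, so integer rounding is a no-op and the
    generated scores equal the mean exactly.
    """
    quiet = mt.RetentionParams(
        mu=20.0, alpha_older=-10.0, gamma_sex=0.0,
        beta1_young=15.0, beta1_older=6.0, beta2_young=18.0, beta2_older=8.0,
        lambda_young=0.0, lambda_older=0.0, rho_retest=3.0,
        delta_young=0.0, delta_older=0.0, sigma_b=0.0, sigma_e=0.0,
    )
    quiet_wp = dataclasses.replace(
        quiet, mu=15.0, alpha_older=-8.0, beta1_young=2.0, beta1_older=1.0,
        beta2_young=4.0, beta2_older=2.0, rho_retest=1.0,
    )
    hp = dataclasses.replace(
        base.hippocampus,
        sd_intercept=1e-9, sd_slope=1e-9, sd_resid=1e-9,
        icv_coef=0.0, sex_effect=0.0,
    )
    return dataclasses.replace(
        base, retention=quiet, transfer=quiet_wp, hippocampus=hp,
        dropout_prob=0.0, wordpair_missing_prob=0.0, visit_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(small_config):
    return mt.simulate_cohort(noiseless_config(small_config), seed=2)
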