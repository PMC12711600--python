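import numpy as np
import pytest

import hydrotraits as ht


@pytest.fixture
def pv_params():
    """Canonical noise-free bench-drying generator settings."""
    return ht.PVGenParams(
        pi0=-1.6, rwc_tlp=0.9, sat_mass=1.0, dry_mass=0.4, n_points=12, seed=0
    )


@pytest.fixture
def vc_series_clean():
    """Noise-free vulnerability observations, psi50 = -3, a = 2."""
    series, truth = ht.gen_vc_observations(
        ht.VCGenParams(psi50_true=-3.0, slope_a=2.0, n_branches=30, seed=0)
    )
    return series, truth


@pytest.fixture
def drydown_clean():
    """Noise-free drydown with sigma = 0.6, intercept = -0.5."""
    series, truth = ht.gen_drydown(
        ht.DrydownGenParams(sigma_true=0.6, intercept_true=-0.5, seed=0)
    )
    return series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
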