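import numpy as np
import pytest

from hdlturnover import KineticRateSet, SHIFTED_TIMES_MIN


@pytest.fixture(scope="session")
def sham_rates():
    """Rate set whose closed-form FCR is 0.24 h^-1 (sham-like turnover)."""
    return KineticRateSet(k_hdl_to_vldl=0.002, k_vldl_to_hdl=0.002,
                          k_hdl_out=0.003, k_vldl_out=0.002)


@pytest.fixture(scope="session")
def ntx_rates():
    """Rate set whose closed-form FCR is 0.14 h^-1 (slow, ntx-like)."""
    return KineticRateSet(k_hdl_to_vldl=0.001, k_vldl_to_hdl=0.001,
                          k_hdl_out=0.002, k_vldl_out=0.0005)


@pytest.fixture(scope="session")
def study_times():
    """The 11-sample schedule with the normalization draw shifted to 0."""
    return np.asarray(SHIFTED_TIMES_MIN)


def random_rate_sets(n, seed, lo=1e-4, hi=0.05):
    """Seeded random rate sets, log-uniform in [lo, hi] min^-1."""
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, 4)))
    return [KineticRateSet(*row) for row in draws]
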