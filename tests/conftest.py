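import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec():
    from accinfo.synthetic_data import default_embryo_spec

    return default_embryo_spec()


@pytest.fixture(scope="session")
def small_embryo_tables():
    """Small replicate set for fast pipeline tests (2 embryos, reduced grid)."""
    from accinfo.synthetic_data import default_embryo_spec, generate_embryos

    spec = default_embryo_spec(n_ap=120, n_dv=8)
    return spec, generate_embryos(spec, 2, seed=42)


@pytest.fixture(scope="session")
def default_embryo_tables():
    """Default-condition replicate set (8 embryos), shared across tests."""
    from accinfo.synthetic_data import default_embryo_spec, generate_embryos

    spec = default_embryo_spec()
    return spec, generate_embryos(spec, 8, seed=7)


def sd_se(sigma: float, n: int) -> float:
    """Standard error of a sample SD of n iid Gaussians (chi-square delta method)."""
    return sigma / np.sqrt(2.0 * (n - 1))
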