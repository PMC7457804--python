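import numpy as np
import pytest

from hcal import france_like, make_prevalence, make_surface

OMEGA = 100


@pytest.fixture(scope="session")
def stationary_surface():
    """Time-constant surface wide enough for cohort tables (rho = 1)."""
    sc = france_like(rho=1.0)
    return make_surface(sc, np.arange(1900, 2101), omega=OMEGA)


@pytest.fixture(scope="session")
def improving_surface():
    """Secularly improving surface, final year 2015."""
    sc = france_like()
    return make_surface(sc, np.arange(1905, 2016), omega=OMEGA)


@pytest.fixture(scope="session")
def logistic_pi():
    """True limitation prevalence on ages 0..100."""
    return make_prevalence(france_like(), np.arange(OMEGA + 1))
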