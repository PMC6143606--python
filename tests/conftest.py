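import numpy as np
import pytest

from sokinetics import (
    ALPCS2,
    ALPCS4,
    DEFAULT_PHYSICAL,
    ExperimentConfig,
)

ALPHA = DEFAULT_PHYSICAL.alpha


@pytest.fixture(scope="session")
def phys():
    return DEFAULT_PHYSICAL


@pytest.fixture(scope="session")
def alpcs2():
    return ALPCS2


@pytest.fixture(scope="session")
def alpcs4():
    return ALPCS4


@pytest.fixture(scope="session")
def table_constants():
    return {"AlPcS2": ALPCS2, "AlPcS4": ALPCS4}


def mv_to_density(phi_mv: float) -> float:
    """Adsorption potential (mV) -> visible-target density (m^-2)."""
    return phi_mv * 1e-3 / ALPHA


@pytest.fixture
def cfg_cis():
    return ExperimentConfig(
        "cis", ps_density=228e12, t0=mv_to_density(20.0), s0=mv_to_density(30.0)
    )


@pytest.fixture
def cfg_trans():
    return ExperimentConfig(
        "trans", ps_density=228e12, t0=mv_to_density(20.0), s0=mv_to_density(30.0)
    )


def random_rate_constants(rng: np.random.Generator, base=ALPCS2, decades=2.0):
    """Rate constants drawn log-uniformly within +-decades around a base set."""
    def draw(x):
        return x * 10.0 ** rng.uniform(-decades, decades)

    return base.replace(
        k_gen=draw(base.k_gen),
        k_so=draw(base.k_so),
        k_to=draw(base.k_to),
        k_ctm=draw(base.k_ctm),
        k_mct=draw(base.k_mct),
        k_w=draw(base.k_w),
        k_w0=draw(base.k_w0),
    )
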