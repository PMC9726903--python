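import numpy as np
import pytest

from serialtoe import DesignSpec, ObserverParams, TruncatedNormal, default_params


@pytest.fixture(scope="session")
def study():
    """The packaged study configuration (observer params, session design)."""
    return default_params()


@pytest.fixture()
def spec():
    return DesignSpec()


@pytest.fixture()
def tiny_spec():
    """Minimal balanced session: one trial per comparison per block."""
    return DesignSpec(trials_per_block=6)


@pytest.fixture()
def noiseless_params():
    """Deterministic observer: zero noise, near-ignorable prior."""
    return ObserverParams(
        q=0.0,
        sigma_subject=TruncatedNormal(0.0, 0.0, -1.0, 1.0),
        prior_var0=1e6,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
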