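import numpy as np
import pytest

import langdyn as ld


@pytest.fixture(scope="session")
def exp1_model():
    return ld.make_model(
        "ecology_society",
        a1=0.08, a2=0.01, K1=1.0, K2=1.0,
        c1=0.04, c2=0.02, alpha=0.6, beta=0.65,
        d1=0.001, d2=0.01,
    )


@pytest.fixture(scope="session")
def exp2_model():
    return ld.make_model(
        "ecology_society",
        a1=0.02, a2=0.01, K1=1.0, K2=1.0,
        c1=0.016, c2=0.02, alpha=0.6, beta=0.5,
        d1=0.005, d2=0.005,
    )


@pytest.fixture(scope="session")
def preset_reports():
    """Both packaged experiments run once at full scale (n=51, dt=0.005)."""
    return {name: ld.run_report(ld.preset(name)) for name in ("exp1", "exp2")}


@pytest.fixture
def rng():
    return np.random.default_rng(20160623)
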