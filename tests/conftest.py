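import numpy as np
import pytest

from nirmetab import (RunConfig, default_library, default_t1d_protocol,
                      generate_visit, run_pipeline)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def t1d_series():
    """One default T1D visit (all four challenge kinds), seed 42."""
    return generate_visit(default_t1d_protocol(), seed=42)


@pytest.fixture(scope="session")
def noiseless_report():
    """Full pipeline with every noise source disabled, fixed k=4."""
    cfg = RunConfig(seed=7, noise_sd=0.0, drift_amplitude=0.0,
                    reference_cv_scale=0.0, k=4)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_report():
    """Default-noise pipeline on the standard T1D visit, master seed 42."""
    return run_pipeline(RunConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
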