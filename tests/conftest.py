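import numpy as np
import pytest

from dscleak import (
    GammaParams,
    PhantomSpec,
    RunConfig,
    make_reference_curve,
)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """No-leakage phantom: K1 = 1 everywhere in brain, K2 = Kep = 0."""
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    """Noise-free phantom whose bolus returns exactly to baseline.

    Recirculation and the steady-state plateau are switched off so the
    degenerate (zero-SD) QC criteria are exactly satisfiable.
    """
    return PhantomSpec(
        noise_sd=0.0,
        gamma_params=GammaParams(recirculation_fraction=0.0, steady_state_level=0.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def reference(default_spec):
    return make_reference_curve(default_spec)


@pytest.fixture(scope="session")
def clean_reference(noiseless_spec):
    return make_reference_curve(noiseless_spec)


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
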