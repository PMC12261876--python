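import numpy as np
import pytest

import preful3d as p


@pytest.fixture(scope="session")
def ideal_profile():
    """Noise-free, perfectly homogeneous scanner."""
    return p.ScannerProfile("ideal", 1.5, snr=np.inf, heterogeneity_scale=0.0)


@pytest.fixture(scope="session")
def noise_free_measurement(ideal_profile):
    """A noise-free constant-sv phantom (sv = 0.25 everywhere in-lung)."""
    spec = p.SubjectSpec(
        "P1", 25.0, "F", "TestCenter", 15.0, 400.0, sv_mean=0.25, seed=11
    )
    return p.simulate_measurement(spec, ideal_profile)


@pytest.fixture(scope="session")
def noisy_measurement():
    spec = p.SubjectSpec(
        "P2", 30.0, "M", "TestCenter", 12.0, 450.0, sv_mean=0.25, seed=21
    )
    prof = p.ScannerProfile("noisy", 3.0, snr=300.0, heterogeneity_scale=1.0)
    return p.simulate_measurement(spec, prof)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
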