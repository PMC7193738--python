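import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS = 1000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def white_noise_60s():
    """60 s of unit-power white noise at 1 kHz (shared, read-only)."""
    x = np.random.default_rng(777).standard_normal(int(60 * FS))
    return x / np.sqrt(np.mean(x**2))


@pytest.fixture(scope="session")
def short_sessions():
    """One 2-minute synthetic session per condition preset (shared)."""
    import dataclasses

    from lpcsep.synthlfp import LEVODOPA_LIKE, SALINE_LIKE, gen_session

    recs = {}
    for name, spec in (("saline", SALINE_LIKE), ("levodopa", LEVODOPA_LIKE)):
        spec2 = dataclasses.replace(spec, duration_min=2.0, seed=99)
        recs[name] = gen_session(spec2, subject_id="m1", condition=name)
    return recs
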